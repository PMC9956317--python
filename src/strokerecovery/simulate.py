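"""Synthetic cohorts for the behavioral and qPCR stages.

The generators emulate a photothrombotic-stroke study in mice: a stroke and a
sham cohort are tested repeatedly on the grid-walk and rotating-beam tasks
(baseline three days before surgery, then days 1-56 post-stroke), and separate
subgroups are sacrificed at days 14, 28 and 56 for qPCR of six target genes
plus a housekeeping gene across four brain regions and both hemispheres.

Every stroke animal carries a latent recovery class (``good`` or ``poor``)
that shapes its one-phase-decay deficit trajectory; the qPCR generator plants
known fold changes between groups and known per-gene amplification
efficiencies.  Ground truth is returned (and written) separately from the
observation tables so the analysis pipeline can never see it.

All randomness flows from a single :class:`numpy.random.Generator` seeded by
the config, so equal configs produce byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorSimConfig",
    "QpcrSimConfig",
    "QpcrDataset",
    "default_behavior_dynamics",
    "default_fold_changes",
    "default_efficiencies",
    "gen_behavior_cohort",
    "gen_qpcr_dataset",
    "write_behavior_tables",
    "write_qpcr_tables",
]

READOUTS = ("foot_fault_pct", "speed_cm_s", "hl_drops")

#: Which behavioral test produces each readout.
READOUT_TEST = {
    "foot_fault_pct": "grid_walk",
    "speed_cm_s": "rotating_beam",
    "hl_drops": "rotating_beam",
}

#: Readouts where a *higher* value means a *worse* deficit.
DEFICIT_HIGH = {"foot_fault_pct": True, "speed_cm_s": False, "hl_drops": True}


def default_behavior_dynamics() -> dict:
    """Per-readout latent trajectory parameters (uniform ranges).

    ``sham`` is the healthy level (also the pre-stroke baseline of every
    animal), ``initial`` the day-3 deficit.  For each latent class,
    ``frac_recovered`` is the fraction of the day-3 deficit recovered at the
    plateau and ``k`` the rate constant per day.  The class ranges are
    disjoint in the induced day-3..14 slope, so a noiseless cohort is
    perfectly separable; magnitudes are sized so the good group sits near a
    50% and the poor group near a 25% recovery score two weeks post-stroke.
    """
    classes = {
        "good": {"frac_recovered": (0.82, 0.92), "k": (0.07, 0.10)},
        "poor": {"frac_recovered": (0.25, 0.35), "k": (0.08, 0.13)},
    }
    return {
        "foot_fault_pct": {"sham": (3.5, 6.5), "initial": (22.0, 28.0), **classes},
        "speed_cm_s": {"sham": (5.5, 6.5), "initial": (2.5, 3.5), **classes},
        "hl_drops": {"sham": (0.2, 0.8), "initial": (3.5, 5.0), **classes},
    }


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Configuration of the behavioral cohort generator.

    Parameters
    ----------
    n_stroke, n_sham : int
        Cohort sizes (defaults 30 and 14).
    frac_good : float
        Fraction of stroke animals assigned the latent ``good`` class.
        Assignment is by exact allocation (``round(frac_good * n_stroke)``
        good animals in shuffled order).
    days : tuple of int
        Measurement days; -3 encodes the pre-stroke baseline session.
    dynamics : dict
        Latent trajectory parameter ranges, see
        :func:`default_behavior_dynamics`.
    trial_noise_sd : dict
        Per-readout Gaussian trial noise (percent for foot faults, cm/s for
        speed, drops for hindlimb drops).
    trials_per_day : dict
        Trials per test and day (4 beam, 1 grid session).
    missing_rate : float
        Probability that an (animal, day, test) observation is lost.
    protect_classification_days : bool
        If True (default), days 3/7/14 are never dropped, so the recovery-rate
        regression always has its inputs; disable to exercise the
        neutral-group path.
    steps_range : (int, int)
        Inclusive range of total steps per grid session.
    beam_length_cm : float
        Rotating-beam length; trial distance.
    """

    n_stroke: int = 30
    n_sham: int = 14
    frac_good: float = 0.5
    days: tuple[int, ...] = (-3, 1, 3, 7, 14, 21, 28, 35, 42, 49, 56)
    dynamics: dict = field(default_factory=default_behavior_dynamics)
    trial_noise_sd: dict = field(
        default_factory=lambda: {"foot_fault_pct": 2.0, "speed_cm_s": 0.5, "hl_drops": 0.8}
    )
    trials_per_day: dict = field(
        default_factory=lambda: {"rotating_beam": 4, "grid_walk": 1}
    )
    missing_rate: float = 0.05
    protect_classification_days: bool = True
    steps_range: tuple[int, int] = (80, 200)
    beam_length_cm: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_good <= 1.0:
            raise ValueError(f"frac_good must be in [0, 1], got {self.frac_good}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if len(self.days) == 0:
            raise ValueError("days must be non-empty")
        post = [d for d in self.days if d >= 0]
        if list(post) != sorted(set(post)):
            raise ValueError("post-stroke days must be strictly increasing")
        for r, sd in self.trial_noise_sd.items():
            if sd < 0:
                raise ValueError(f"trial_noise_sd[{r}] must be >= 0")
        for r, spec in self.dynamics.items():
            for cls in ("good", "poor"):
                k_lo, k_hi = spec[cls]["k"]
                if k_lo < 0 or k_hi < 0:
                    raise ValueError(f"rate constants must be >= 0 ({r}/{cls})")

    def with_(self, **kwargs) -> "BehaviorSimConfig":
        """Return a copy with fields replaced."""
        return replace(self, **kwargs)


def _latent_value(base, initial, frac, k, day):
    """Latent readout value on a post-stroke day.

    The deficit peaks at day 3 (``initial``) and relaxes as a one-phase
    exponential toward ``plateau = initial + frac * (base - initial)`` with
    rate ``k`` per day; days 1..3 sit at the peak.
    """
    dt = max(float(day) - 3.0, 0.0)
    return initial + frac * (base - initial) * (1.0 - math.exp(-k * dt))


def gen_behavior_cohort(config: BehaviorSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate behavioral trial records plus the latent ground truth.

    Returns
    -------
    trials : DataFrame
        One row per trial with columns ``animal_id, cohort, latent_class,
        day, test, trial, duration_s, distance_cm, hindlimb_drops, steps,
        foot_faults``.  Beam rows have null grid fields and vice versa.
    truth : DataFrame
        Per animal and readout: latent class, baseline, initial deficit,
        plateau and rate constant.  Never consumed by the pipeline.
    """
    rng = np.random.default_rng(config.seed)
    n_s, n_h = config.n_stroke, config.n_sham

    animals = [f"S{i + 1:03d}" for i in range(n_s)] + [f"H{i + 1:03d}" for i in range(n_h)]
    cohorts = ["stroke"] * n_s + ["sham"] * n_h

    n_good = int(round(config.frac_good * n_s))
    latent = np.array(["good"] * n_good + ["poor"] * (n_s - n_good), dtype=object)
    rng.shuffle(latent)
    classes = list(latent) + [""] * n_h

    # Per-animal latent parameters, drawn readout by readout.
    params: dict[str, dict[str, np.ndarray]] = {}
    for readout in READOUTS:
        spec = config.dynamics[readout]
        base = rng.uniform(*spec["sham"], size=len(animals))
        initial = rng.uniform(*spec["initial"], size=len(animals))
        frac = np.zeros(len(animals))
        k = np.zeros(len(animals))
        for i, cls in enumerate(classes):
            if cls:
                frac[i] = rng.uniform(*spec[cls]["frac_recovered"])
                k[i] = rng.uniform(*spec[cls]["k"])
        params[readout] = {"base": base, "initial": initial, "frac": frac, "k": k}

    rows = []
    protected = {3, 7, 14} if config.protect_classification_days else set()
    for i, animal in enumerate(animals):
        cohort, cls = cohorts[i], classes[i]
        for day in config.days:
            for test in ("grid_walk", "rotating_beam"):
                missing = (
                    config.missing_rate > 0
                    and day not in protected
                    and rng.random() < config.missing_rate
                )
                n_trials = config.trials_per_day[test]
                for trial in range(1, n_trials + 1):
                    if test == "grid_walk":
                        p = params["foot_fault_pct"]
                        steps = int(rng.integers(config.steps_range[0], config.steps_range[1] + 1))
                        lat = (
                            p["base"][i]
                            if cohort == "sham" or day < 0
                            else _latent_value(p["base"][i], p["initial"][i], p["frac"][i], p["k"][i], day)
                        )
                        sd = config.trial_noise_sd["foot_fault_pct"]
                        pct = lat if sd == 0 else lat + rng.normal(0.0, sd)
                        pct = min(max(pct, 0.0), 100.0)
                        faults = int(round(steps * pct / 100.0))
                        row = dict(duration_s=np.nan, distance_cm=np.nan,
                                   hindlimb_drops=pd.NA, steps=steps, foot_faults=faults)
                    else:
                        ps, pd_ = params["speed_cm_s"], params["hl_drops"]
                        if cohort == "sham" or day < 0:
                            lat_speed, lat_drops = ps["base"][i], pd_["base"][i]
                        else:
                            lat_speed = _latent_value(ps["base"][i], ps["initial"][i], ps["frac"][i], ps["k"][i], day)
                            lat_drops = _latent_value(pd_["base"][i], pd_["initial"][i], pd_["frac"][i], pd_["k"][i], day)
                        sd_v = config.trial_noise_sd["speed_cm_s"]
                        sd_d = config.trial_noise_sd["hl_drops"]
                        speed = lat_speed if sd_v == 0 else lat_speed + rng.normal(0.0, sd_v)
                        speed = max(speed, 0.3)  # the mouse always moves eventually
                        drops = lat_drops if sd_d == 0 else lat_drops + rng.normal(0.0, sd_d)
                        drops = int(round(max(drops, 0.0)))
                        row = dict(duration_s=config.beam_length_cm / speed,
                                   distance_cm=config.beam_length_cm,
                                   hindlimb_drops=drops, steps=pd.NA, foot_faults=pd.NA)
                    if missing:
                        continue
                    rows.append(dict(animal_id=animal, cohort=cohort, latent_class=cls,
                                     day=day, test=test, trial=trial, **row))

    trials = pd.DataFrame(rows)
    trials["hindlimb_drops"] = trials["hindlimb_drops"].astype("Int64")
    trials["steps"] = trials["steps"].astype("Int64")
    trials["foot_faults"] = trials["foot_faults"].astype("Int64")

    truth_rows = []
    for i, animal in enumerate(animals):
        for readout in READOUTS:
            p = params[readout]
            plateau = (
                p["initial"][i] + p["frac"][i] * (p["base"][i] - p["initial"][i])
                if classes[i]
                else p["base"][i]
            )
            truth_rows.append(dict(
                animal_id=animal, cohort=cohorts[i], latent_class=classes[i],
                readout=readout, baseline=p["base"][i],
                initial=p["initial"][i] if classes[i] else p["base"][i],
                plateau=plateau, k=p["k"][i],
            ))
    truth = pd.DataFrame(truth_rows)
    return trials, truth


# ---------------------------------------------------------------------------
# qPCR generator
# ---------------------------------------------------------------------------

GENES = ("Adora2a", "Pde10a", "Drd2", "Lingo1", "Atrx", "BDNF")
REGIONS = ("MOp", "SSp", "Str", "TH")
HEMISPHERES = ("il", "cl")
ENDPOINTS = (14, 28, 56)


def default_fold_changes() -> dict:
    """True expression ratios vs. sham, keyed (gene, region, hemi, endpoint, group).

    The well-recovered group is left at the sham level; the poorly recovered
    group carries the contralesional fold changes reported for this study
    design (e.g. Adora2a 4.5x in cl-MOp at day 14, Drd2 7.5x, Pde10a 2.4x in
    cl-Str at day 56, Lingo1 0.6x in cl-MOp at day 14).  Contrasts described
    as significant but without a printed factor are set to a modest 1.5-2
    fold; everything else is 1.
    """
    poor_cl = {
        ("Adora2a", "MOp", 14): 4.5,
        ("Adora2a", "MOp", 56): 2.3,
        ("Pde10a", "MOp", 14): 2.0,
        ("Pde10a", "MOp", 56): 2.0,
        ("Drd2", "MOp", 14): 7.5,
        ("Lingo1", "MOp", 14): 0.6,
        ("Lingo1", "MOp", 56): 1.2,
        ("Atrx", "MOp", 28): 1.5,
        ("BDNF", "MOp", 14): 0.6,
        ("Adora2a", "SSp", 28): 0.6,
        ("Pde10a", "SSp", 28): 0.3,
        ("Drd2", "SSp", 28): 0.6,
        ("Lingo1", "SSp", 28): 1.5,
        ("BDNF", "SSp", 28): 1.7,
        ("Adora2a", "Str", 14): 0.5,
        ("Adora2a", "Str", 56): 1.7,
        ("Pde10a", "Str", 14): 0.5,
        ("Pde10a", "Str", 28): 2.0,
        ("Pde10a", "Str", 56): 2.4,
        ("Drd2", "Str", 14): 0.5,
        ("Drd2", "Str", 28): 2.0,
        ("Lingo1", "Str", 14): 2.0,
        ("Lingo1", "Str", 28): 0.5,
        ("BDNF", "Str", 14): 1.5,
        ("BDNF", "Str", 28): 0.6,
        ("BDNF", "Str", 56): 0.6,
        ("Adora2a", "TH", 14): 2.0,
        ("Adora2a", "TH", 56): 0.6,
        ("Pde10a", "TH", 14): 2.0,
        ("Pde10a", "TH", 56): 0.5,
        ("Drd2", "TH", 14): 2.0,
        ("Drd2", "TH", 56): 0.5,
        ("Lingo1", "TH", 14): 1.2,
        ("BDNF", "TH", 14): 0.6,
        ("BDNF", "TH", 56): 1.5,
    }
    table = {}
    for (gene, region, day), ratio in poor_cl.items():
        table[(gene, region, "cl", day, "poor")] = ratio
    return table


def default_efficiencies() -> dict:
    """Realistic per-gene amplification efficiencies (per-cycle factor)."""
    return {
        "Gapdh": 2.00, "Adora2a": 1.95, "Pde10a": 1.90, "Drd2": 1.92,
        "Lingo1": 1.88, "Atrx": 1.94, "BDNF": 1.85,
    }


def _default_n_per_group() -> dict:
    return {14: {"good": 5, "poor": 4, "sham": 5},
            28: {"good": 3, "poor": 2, "sham": 3},
            56: {"good": 4, "poor": 3, "sham": 5}}


_BASE_CQ = {"Gapdh": 18.0, "Adora2a": 26.0, "Pde10a": 25.0, "Drd2": 27.0,
            "Lingo1": 24.0, "Atrx": 23.0, "BDNF": 26.0}


@dataclass(frozen=True)
class QpcrSimConfig:
    """Configuration of the Cq-table / dilution-series generator.

    ``group_fold_change`` maps ``(gene, region, hemisphere, endpoint, group)``
    to the true expression ratio vs. sham (missing keys mean 1.0; the
    reference gene must not appear).  ``replicate_sd`` is the technical-well
    Cq noise in cycles, ``animal_sd`` the biological between-animal noise.
    """

    genes: tuple[str, ...] = GENES
    reference_gene: str = "Gapdh"
    regions: tuple[str, ...] = REGIONS
    hemispheres: tuple[str, ...] = HEMISPHERES
    endpoints: tuple[int, ...] = ENDPOINTS
    group_fold_change: Mapping = field(default_factory=default_fold_changes)
    efficiency_true: Mapping[str, float] = field(default_factory=default_efficiencies)
    replicate_sd: float = 0.3
    animal_sd: float = 0.2
    n_replicates: int = 3
    n_per_group: Mapping = field(default_factory=_default_n_per_group)
    dilution_amounts: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 50.0, 100.0, 200.0)
    dilution_replicates: int = 3
    dilution_anchor_ng: float = 20.0
    seed: int = 0

    def __post_init__(self):
        for gene in (*self.genes, self.reference_gene):
            e = self.efficiency_true.get(gene)
            if e is None:
                raise ValueError(f"efficiency_true missing for {gene}")
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency must be in (1, 2], got {e} for {gene}")
        for key, ratio in self.group_fold_change.items():
            if ratio <= 0:
                raise ValueError(f"fold change must be > 0, got {ratio} for {key}")
            if key[0] == self.reference_gene:
                raise ValueError("reference gene must be unregulated")
        if self.replicate_sd < 0 or self.animal_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def with_(self, **kwargs) -> "QpcrSimConfig":
        return replace(self, **kwargs)


@dataclass
class QpcrDataset:
    """Observation tables plus the hidden ground truth of a simulated run."""

    cq: pd.DataFrame
    dilution: pd.DataFrame
    truth_fold_changes: pd.DataFrame
    truth_efficiencies: pd.DataFrame


def gen_qpcr_dataset(config: QpcrSimConfig) -> QpcrDataset:
    """Generate Cq measurements and a dilution series with known truth.

    The Cq model is ``cq = base_g - log_E(R) + animal effect + well noise``
    where ``R`` is the animal's true expression relative to sham and ``E`` the
    gene's amplification efficiency, so every downstream estimator inverts
    the generator exactly when the noise terms are zero.  The dilution series
    follows ``cq = base_g - log10(ng / anchor) / log10(E)`` with 0 ng rows
    emitted as flagged no-template controls.
    """
    rng = np.random.default_rng(config.seed)
    all_genes = (*config.genes, config.reference_gene)
    log_e = {g: math.log(config.efficiency_true[g]) for g in all_genes}

    rows = []
    for endpoint in config.endpoints:
        counts = config.n_per_group[endpoint]
        for group in sorted(counts):
            for idx in range(counts[group]):
                animal = f"Q{endpoint}{group[0].upper()}{idx + 1:02d}"
                for region in config.regions:
                    for hemi in config.hemispheres:
                        for gene in all_genes:
                            if gene == config.reference_gene or group == "sham":
                                ratio = 1.0
                            else:
                                ratio = config.group_fold_change.get(
                                    (gene, region, hemi, endpoint, group), 1.0)
                            mu = _BASE_CQ.get(gene, 25.0) - math.log(ratio) / log_e[gene]
                            if config.animal_sd > 0:
                                mu += rng.normal(0.0, config.animal_sd)
                            for rep in range(1, config.n_replicates + 1):
                                cq = mu
                                if config.replicate_sd > 0:
                                    cq += rng.normal(0.0, config.replicate_sd)
                                rows.append(dict(
                                    animal_id=animal, group=group, endpoint_day=endpoint,
                                    region=region, hemisphere=hemi, gene=gene,
                                    replicate=rep, cq=cq))
    cq_df = pd.DataFrame(rows)

    dil_rows = []
    for gene in all_genes:
        slope = -1.0 / math.log10(config.efficiency_true[gene])
        for ng in config.dilution_amounts:
            for rep in range(1, config.dilution_replicates + 1):
                if ng == 0:
                    dil_rows.append(dict(gene=gene, input_ng=0.0, replicate=rep,
                                         cq=np.nan, is_ntc=True))
                else:
                    cq = _BASE_CQ.get(gene, 25.0) + slope * math.log10(ng / config.dilution_anchor_ng)
                    if config.replicate_sd > 0:
                        cq += rng.normal(0.0, config.replicate_sd)
                    dil_rows.append(dict(gene=gene, input_ng=float(ng), replicate=rep,
                                         cq=cq, is_ntc=False))
    dilution = pd.DataFrame(dil_rows)

    truth_fc = pd.DataFrame(
        [dict(gene=g, region=r, hemisphere=h, endpoint_day=d, group=grp, fold_change=v)
         for (g, r, h, d, grp), v in sorted(config.group_fold_change.items())]
    )
    if truth_fc.empty:
        truth_fc = pd.DataFrame(
            columns=["gene", "region", "hemisphere", "endpoint_day", "group", "fold_change"])
    truth_eff = pd.DataFrame(
        [dict(gene=g, efficiency=config.efficiency_true[g]) for g in all_genes]
    )
    return QpcrDataset(cq_df, dilution, truth_fc, truth_eff)


# ---------------------------------------------------------------------------
# CSV writers
# ---------------------------------------------------------------------------

def write_behavior_tables(trials: pd.DataFrame, truth: pd.DataFrame, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [outdir / "trials.csv", outdir / "truth_behavior.csv"]
    trials.to_csv(paths[0], index=False)
    truth.to_csv(paths[1], index=False)
    return paths


def write_qpcr_tables(dataset: QpcrDataset, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [outdir / "cq.csv", outdir / "dilution.csv",
             outdir / "truth_fold_changes.csv", outdir / "truth_efficiencies.csv"]
    dataset.cq.to_csv(paths[0], index=False)
    dataset.dilution.to_csv(paths[1], index=False)
    dataset.truth_fold_changes.to_csv(paths[2], index=False)
    dataset.truth_efficiencies.to_csv(paths[3], index=False)
    return paths
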