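"""End-to-end orchestration: synthesis -> behavior -> qPCR -> report.

A run is driven by a :class:`RunConfig` (usually loaded from YAML), executes
the stages in order, and writes every output CSV with a JSON provenance
sidecar carrying the config hash, seed and package version — no timestamps,
so a rerun with the same config and seed is bit-identical.  A stage failure
aborts with a stage-specific exit code and quarantines that stage's partial
outputs under ``quarantine/``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import classify_cohort, daily_readouts, recovery_scores, sham_reference
from .decay import extra_ss_f_test, fit_one_phase_decay
from .errors import StageError
from .qpcr import efficiency_table, relative_expression_table
from .simulate import (BehaviorSimConfig, QpcrSimConfig, gen_behavior_cohort,
                       gen_qpcr_dataset)

__all__ = ["RunConfig", "run_pipeline", "render_direction_table", "EXIT_CODES"]

logger = logging.getLogger(__name__)

EXIT_CODES = {"config": 2, "synth": 3, "behavior": 4, "qpcr": 5, "report": 6}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either synthetic generation (``synth=True``, with optional parameter
    overrides) or user tables (``trials``/``cq``/``dilution`` paths) feed the
    pipeline.  ``seed`` drives every stochastic stage and is mandatory.
    """

    outdir: str = "run"
    seed: int = 0
    synth: bool = True
    synth_behavior: dict = field(default_factory=dict)
    synth_qpcr: dict = field(default_factory=dict)
    trials: str | None = None
    cq: str | None = None
    dilution: str | None = None
    slope_mode: str = "three_point_preferred"
    tie_vote: str = "poor"
    n_perm: int = 10000
    exhaustive_cap: int = 20000
    bootstrap: int = 1000
    alpha: float = 0.05
    force_e2: bool = False
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise StageError("config", EXIT_CODES["config"],
                             f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise StageError("config", EXIT_CODES["config"], str(exc))
        if cfg.seed is None:
            raise StageError("config", EXIT_CODES["config"], "seed is mandatory")
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        The output location and log level do not affect results and are
        excluded, so runs in different directories compare equal.
        """
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        d.pop("verbosity", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class _StageWriter:
    """Tracks files written per stage so failures can be quarantined."""

    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.meta = {"config_hash": config.config_hash(), "seed": config.seed,
                     "package_version": __version__}
        self.written: list[Path] = []

    def write(self, df: pd.DataFrame, name: str, stage: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        payload = dict(self.meta, file=name, stage=stage, rows=len(df))
        sidecar.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")
        self.written += [path, sidecar]
        return path

    def quarantine(self, stage_files: list[Path]):
        qdir = self.outdir / "quarantine"
        qdir.mkdir(exist_ok=True)
        for f in stage_files:
            if f.exists():
                shutil.move(str(f), qdir / f.name)


def _stage(name):
    """Decorator: log timing and convert stage failures to StageError."""

    def deco(fn):
        def wrapper(ctx, *args, **kwargs):
            t0 = time.perf_counter()
            before = list(ctx["writer"].written)
            try:
                out = fn(ctx, *args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                new = [f for f in ctx["writer"].written if f not in before]
                ctx["writer"].quarantine(new)
                raise StageError(name, EXIT_CODES[name], str(exc)) from exc
            logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("synth")
def _run_synth(ctx):
    cfg: RunConfig = ctx["config"]
    w: _StageWriter = ctx["writer"]
    bseed, qseed = ctx["seeds"]["synth_behavior"], ctx["seeds"]["synth_qpcr"]
    bcfg = BehaviorSimConfig(**{"seed": bseed, **cfg.synth_behavior})
    trials, truth_b = gen_behavior_cohort(bcfg)
    w.write(trials, "trials.csv", "synth")
    w.write(truth_b, "truth_behavior.csv", "synth")
    qcfg_kwargs = dict(cfg.synth_qpcr)
    qcfg = QpcrSimConfig(**{"seed": qseed, **qcfg_kwargs})
    ds = gen_qpcr_dataset(qcfg)
    w.write(ds.cq, "cq.csv", "synth")
    w.write(ds.dilution, "dilution.csv", "synth")
    w.write(ds.truth_fold_changes, "truth_fold_changes.csv", "synth")
    w.write(ds.truth_efficiencies, "truth_efficiencies.csv", "synth")
    ctx["trials"] = trials
    ctx["cq"] = ds.cq
    ctx["dilution"] = ds.dilution


@_stage("behavior")
def _run_behavior(ctx):
    cfg: RunConfig = ctx["config"]
    w: _StageWriter = ctx["writer"]
    trials = ctx.get("trials")
    if trials is None:
        if not cfg.trials or not Path(cfg.trials).exists():
            raise FileNotFoundError(f"trials table not found: {cfg.trials!r}")
        trials = pd.read_csv(cfg.trials)
    readouts = daily_readouts(trials)
    w.write(readouts, "readouts.csv", "behavior")

    stroke = readouts[readouts["cohort"] == "stroke"]
    classes = classify_cohort(stroke, slope_mode=cfg.slope_mode, tie_vote=cfg.tie_vote)
    rates = classes[[c for c in classes.columns if c.startswith(("animal_id", "slope_", "n_points_"))]]
    w.write(rates, "rates.csv", "behavior")
    w.write(classes, "classes.csv", "behavior")

    scores = recovery_scores(readouts, sham_reference(readouts))
    w.write(scores, "scores.csv", "behavior")

    labels = classes.set_index("animal_id")["label"]
    scored = scores.assign(label=scores["animal_id"].map(labels))
    fits, pooled_pts = [], []
    for group in ("good", "poor"):
        pts = scored[scored["label"] == group]
        if len(pts) >= 4:
            fit = fit_one_phase_decay((pts["day"].to_numpy(), pts["score"].to_numpy()))
            fits.append((group, fit))
            pooled_pts.append(pts)
    ftest = None
    if len(fits) == 2:
        pooled = pd.concat(pooled_pts)
        shared = fit_one_phase_decay((pooled["day"].to_numpy(), pooled["score"].to_numpy()))
        ftest = extra_ss_f_test(shared, [f for _, f in fits])
        fits.append(("shared", shared))
    fit_rows = [dict(group=g, y0=f.y0, plateau=f.plateau, k=f.k, rss=f.rss, df=f.df, n=f.n)
                for g, f in fits]
    fit_df = pd.DataFrame(fit_rows)
    if ftest is not None:
        fit_df["f_shared_vs_separate"] = ftest.f
        fit_df["p_shared_vs_separate"] = ftest.p
    w.write(fit_df, "decay_fits.csv", "behavior")
    ctx["classes"] = classes
    ctx["decay_fits"] = fit_df
    ctx["ftest"] = ftest


@_stage("qpcr")
def _run_qpcr(ctx):
    cfg: RunConfig = ctx["config"]
    w: _StageWriter = ctx["writer"]
    cq = ctx.get("cq")
    if cq is None:
        if not cfg.cq or not Path(cfg.cq).exists():
            raise FileNotFoundError(f"cq table not found: {cfg.cq!r}")
        cq = pd.read_csv(cfg.cq)
    dilution = ctx.get("dilution")
    if dilution is None and cfg.dilution and Path(cfg.dilution).exists():
        dilution = pd.read_csv(cfg.dilution)

    eff = None
    if dilution is not None:
        eff = efficiency_table(dilution)
        w.write(eff, "efficiencies.csv", "qpcr")
    ratios = relative_expression_table(
        cq, efficiencies=eff, n_perm=cfg.n_perm, exhaustive_cap=cfg.exhaustive_cap,
        bootstrap=cfg.bootstrap, seed=ctx["seeds"]["qpcr"], force_e2=cfg.force_e2)
    w.write(ratios, "ratios.csv", "qpcr")
    ctx["ratios"] = ratios


def render_direction_table(ratios: pd.DataFrame, alpha: float = 0.05
                           ) -> tuple[pd.DataFrame, str]:
    """Direction-of-change summary for the contralesional poor-vs-good contrast.

    One row per (gene, cl region, endpoint): ``up_in_poor`` when the
    poor-relative-to-good ratio exceeds 1 at ``p < alpha``, ``down_in_poor``
    when below 1, ``ns`` otherwise, and ``nd`` (not determined) when the
    contrast is missing.  Returns the table plus a plain-text grid.
    """
    sel = ratios[(ratios["sample_group"] == "poor")
                 & (ratios["control_group"] == "good")
                 & (ratios["hemisphere"] == "cl")]
    genes = sorted(ratios["gene"].unique())
    regions = sorted(ratios["region"].unique())
    endpoints = sorted(ratios["endpoint_day"].unique())
    idx = {(r.gene, r.region, r.endpoint_day): r for r in sel.itertuples(index=False)}
    rows = []
    for gene in genes:
        for region in regions:
            for day in endpoints:
                r = idx.get((gene, region, day))
                if r is None:
                    direction, ratio, p = "nd", np.nan, np.nan
                elif r.p < alpha:
                    direction = "up_in_poor" if r.ratio > 1 else "down_in_poor"
                    ratio, p = r.ratio, r.p
                else:
                    direction, ratio, p = "ns", r.ratio, r.p
                rows.append(dict(gene=gene, region=region, endpoint_day=day,
                                 direction=direction, ratio=ratio, p=p))
    table = pd.DataFrame(rows)

    mark = {"up_in_poor": "up", "down_in_poor": "down", "ns": "ns", "nd": "nd"}
    cols = [f"{region}-P{day}" for region in regions for day in endpoints]
    width = max(len(c) for c in cols) + 2
    lines = ["gene".ljust(10) + "".join(c.rjust(width) for c in cols)]
    for gene in genes:
        cells = []
        for region in regions:
            for day in endpoints:
                d = table[(table["gene"] == gene) & (table["region"] == region)
                          & (table["endpoint_day"] == day)]["direction"].iloc[0]
                cells.append(mark[d].rjust(width))
        lines.append(gene.ljust(10) + "".join(cells))
    return table, "\n".join(lines) + "\n"


@_stage("report")
def _run_report(ctx):
    cfg: RunConfig = ctx["config"]
    w: _StageWriter = ctx["writer"]
    table, text = render_direction_table(ctx["ratios"], alpha=cfg.alpha)
    w.write(table, "direction_table.csv", "report")
    txt_path = w.outdir / "direction_table.txt"
    txt_path.write_text(text)
    w.written.append(txt_path)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and return the artifact directory."""
    logging.basicConfig(level=getattr(logging, str(config.verbosity).upper(), logging.INFO),
                        format="%(levelname)s %(name)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(config.seed)
    kids = root.spawn(3)
    seeds = {"synth_behavior": int(kids[0].generate_state(1)[0] % (2 ** 31)),
             "synth_qpcr": int(kids[1].generate_state(1)[0] % (2 ** 31)),
             "qpcr": int(kids[2].generate_state(1)[0] % (2 ** 31))}

    ctx = {"config": config, "writer": _StageWriter(outdir, config), "seeds": seeds}
    logger.info("run config_hash=%s seed=%s alpha=%s n_perm=%s slope_mode=%s",
                config.config_hash(), config.seed, config.alpha, config.n_perm,
                config.slope_mode)
    if config.synth:
        _run_synth(ctx)
    _run_behavior(ctx)
    _run_qpcr(ctx)
    _run_report(ctx)
    return outdir
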