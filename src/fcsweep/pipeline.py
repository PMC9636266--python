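"""End-to-end orchestration: configuration, I/O, logging, provenance.

``run_full_pipeline`` executes the whole analysis on either a synthetic
cohort or a directory of precomputed connectivity matrices:

    recordings -> connectivity matrices -> quantile sweep -> graph metrics
    -> edge-probability graphs -> OMST + matched-density comparison
    -> regressions / group profiles / descriptives

Everything is written as delimited text plus a JSON manifest holding the
resolved configuration, package version and master seed, so a rerun with
the same config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edgeprob import (
    edge_probabilities,
    edgeprob_long_frame,
    scale_across_thresholds,
)
from .metrics import add_metrics, compute_metrics
from .omst import extract_orthogonal_msts, match_density_threshold
from .spectral import (
    ALPHA_BAND,
    ConnectivityMatrix,
    band_connectivity,
    load_connectivity,
    save_connectivity,
)
from .stats import (
    compare_omst_vs_matched,
    connectivity_descriptives,
    fit_density_regression,
    group_effect_profile,
)
from .synthcohort import (
    CohortSpec,
    GroupEffect,
    generate_cohort,
    modular_oscillator_spec,
    save_cohort,
)
from .thresholding import DEFAULT_Q_GRID, run_sweep

__all__ = ["PipelineConfig", "run_full_pipeline", "read_connectivity_dir"]

logger = logging.getLogger("fcsweep")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "fcsweep_out"
    seed: int = 0
    # synthetic cohort (used unless connectivity_dir is given)
    connectivity_dir: str | None = None
    n_channels: int = 32
    n_modules: int = 4
    followers_per_module: int = 6
    coupling_strength: float = 0.6
    noise_sd: float = 1.0
    duration: float = 120.0
    sfreq: float = 256.0
    n_subjects_per_group: int = 10
    subject_variability_sd: float = 0.1
    group_effect_parameter: str = "coupling_strength"
    group_effect_delta: float = 0.0
    save_recordings: bool = False
    # estimation
    measures: tuple[str, ...] = ("wpli", "imcoh", "coherence", "ciplv", "ppc")
    band: tuple[float, float] = ALPHA_BAND
    epoch_length: int = 512
    rectify: str = "default"
    # sweep / metrics
    q_step: float = 0.01
    metric_set: tuple[str, ...] = ("cpl", "clustering", "participation", "swi")
    swi_refs: int = 20
    # statistics
    n_permutations: int = 10_000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.q_step < 1):
            raise ValueError("q_step must lie in (0, 1)")
        if self.epoch_length < 2:
            raise ValueError("epoch_length must be >= 2 samples")
        bad = [m for m in self.measures if m not in
               ("wpli", "imcoh", "coherence", "ciplv", "ppc")]
        if bad:
            raise ValueError(f"unknown measures: {bad}")

    @property
    def q_grid(self) -> tuple[float, ...]:
        if abs(self.q_step - 0.01) < 1e-12:
            return DEFAULT_Q_GRID
        n = int(round((1.0 - self.q_step) / self.q_step))
        return tuple(np.round(np.arange(1, n + 1) * self.q_step, 10))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("measures", "band", "metric_set"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("measures", "band", "metric_set"):
            d[key] = list(d[key])
        return d


def read_connectivity_dir(path: str | Path, strict: bool = True) -> list[ConnectivityMatrix]:
    """Load and validate every ``<subject>_<measure>.csv`` in a directory.

    Symmetry within 1e-9 is enforced and the diagonal zeroed.  With
    ``strict=False`` invalid files are skipped with a warning instead of
    aborting.  A ``groups.csv`` (subject_id, group) in the directory, if
    present, attaches group labels.
    """
    path = Path(path)
    files = sorted(path.glob("*_*.csv"))
    groups: dict[str, str] = {}
    gfile = path / "groups.csv"
    if gfile.exists():
        gdf = pd.read_csv(gfile)
        groups = dict(zip(gdf["subject_id"].astype(str), gdf["group"].astype(str)))
    matrices = []
    for f in files:
        if f.name == "groups.csv":
            continue
        try:
            m = load_connectivity(f)
            m.group = groups.get(m.subject_id, "")
            matrices.append(m)
        except ValueError as exc:
            if strict:
                raise
            warnings.warn(f"skipping {f.name}: {exc}", stacklevel=2)
    if not matrices:
        raise ValueError(f"no valid connectivity matrices in {path}")
    return matrices


def _simulate_stage(cfg: PipelineConfig, out: Path):
    base = modular_oscillator_spec(
        n_channels=cfg.n_channels,
        n_modules=cfg.n_modules,
        followers_per_module=cfg.followers_per_module,
        strength=cfg.coupling_strength,
        noise_sd=cfg.noise_sd,
        duration=cfg.duration,
        sfreq=cfg.sfreq,
        seed=cfg.seed,
    )
    cohort = CohortSpec(
        n_subjects_per_group=cfg.n_subjects_per_group,
        group_effect=GroupEffect(parameter=cfg.group_effect_parameter,
                                 delta=cfg.group_effect_delta),
        subject_variability_sd=cfg.subject_variability_sd,
        seed=cfg.seed,
    )
    recordings = generate_cohort(cohort, base, epoch_length=cfg.epoch_length)
    if cfg.save_recordings:
        save_cohort(recordings, out / "recordings")
    return recordings


def run_full_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage and write all artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        # -- connectivity ---------------------------------------------------
        stage = "connectivity"
        matrices: list[ConnectivityMatrix] = []
        if cfg.connectivity_dir is not None:
            matrices = read_connectivity_dir(cfg.connectivity_dir)
            subjects = sorted({m.subject_id for m in matrices})
            by_subject = {s: [m for m in matrices if m.subject_id == s] for s in subjects}
            want = set(cfg.measures)
            for s, ms in by_subject.items():
                have = {m.measure for m in ms}
                if not want <= have:
                    raise RuntimeError(
                        f"stage {stage}: subject {s} missing measures {sorted(want - have)}"
                    )
            matrices = [m for m in matrices if m.measure in want]
        else:
            recordings = _simulate_stage(cfg, out)
            logger.info("simulated %d recordings", len(recordings))
            for rec in recordings:
                for measure in cfg.measures:
                    try:
                        matrices.append(
                            band_connectivity(
                                rec, measure, band=cfg.band,
                                epoch_length=cfg.epoch_length,
                                rectify=cfg.rectify,
                            )
                        )
                    except ValueError as exc:
                        raise RuntimeError(
                            f"stage {stage}: subject {rec.subject_id}: {exc}"
                        ) from exc
        conn_dir = out / "connectivity"
        for m in matrices:
            save_connectivity(m, conn_dir)
        groups_present = sorted({m.group for m in matrices if m.group})
        if groups_present:
            gdf = pd.DataFrame(
                sorted({(m.subject_id, m.group) for m in matrices}),
                columns=["subject_id", "group"],
            )
            gdf.to_csv(conn_dir / "groups.csv", index=False)
        logger.info("connectivity: %d matrices (%.1f s)", len(matrices), time.time() - t0)

        # -- descriptives ---------------------------------------------------
        stage = "descriptives"
        desc = pd.DataFrame([dataclasses.asdict(connectivity_descriptives(m))
                             for m in matrices])
        desc.to_csv(out / "descriptives.csv", index=False)

        # -- sweep + metrics ------------------------------------------------
        stage = "sweep"
        sweep = run_sweep(matrices, q_grid=cfg.q_grid)
        add_metrics(sweep, n_random_refs=cfg.swi_refs, master_seed=cfg.seed,
                    which=cfg.metric_set)
        sweep_df = sweep.to_frame()
        sweep_df.to_csv(out / "sweep.csv", index=False)
        logger.info("sweep: %d records (%.1f s)", len(sweep_df), time.time() - t0)

        # -- edge probability -----------------------------------------------
        stage = "edgeprob"
        labels = matrices[0].node_labels
        ep_dir = out / "edgeprob"
        ep_dir.mkdir(exist_ok=True)
        ep_frames = []
        for measure in cfg.measures:
            eps = []
            for q in cfg.q_grid:
                graphs = sweep.at(q, measure)
                if graphs:
                    eps.append(edge_probabilities(graphs, labels, measure, q))
            scale_across_thresholds(eps)
            ep_frames.append(edgeprob_long_frame(eps))
        pd.concat(ep_frames).to_csv(ep_dir / "edge_probabilities.csv", index=False)

        # -- OMST -----------------------------------------------------------
        stage = "omst"
        omst_rows, matched_rows, trace_rows = [], [], []
        omst_graphs: dict[str, list] = {m_: [] for m_ in cfg.measures}
        for k, m in enumerate(matrices):
            try:
                res = extract_orthogonal_msts(m)
            except ValueError as exc:
                raise RuntimeError(
                    f"stage {stage}: subject {m.subject_id}/{m.measure}: {exc}"
                ) from exc
            omst_graphs[m.measure].append(res)
            matched = match_density_threshold(m, res.density, q_grid=cfg.q_grid)
            for tag, g in (("omst", res.union_graph), ("matched", matched.graph)):
                rec = compute_metrics(
                    g, n_random_refs=cfg.swi_refs,
                    seed=(cfg.seed * 1_000_003 + 7919 * k) % (2**31),
                    which=cfg.metric_set, strict=False,
                )
                row = {"subject": m.subject_id, "group": m.group,
                       "measure": m.measure, "cpl": rec.cpl,
                       "clustering": rec.clustering,
                       "participation": rec.participation, "swi": rec.swi}
                (omst_rows if tag == "omst" else matched_rows).append(
                    {**row, "density": res.density if tag == "omst" else matched.density,
                     "q": np.nan if tag == "omst" else matched.q}
                )
            for (m_idx, cost, ge, j) in res.gce_trace:
                trace_rows.append({"subject": m.subject_id, "measure": m.measure,
                                   "m": m_idx, "cost": cost, "global_efficiency": ge,
                                   "J": j, "selected": m_idx == res.selected_m})
        omst_dir = out / "omst"
        omst_dir.mkdir(exist_ok=True)
        omst_df = pd.DataFrame(omst_rows)
        matched_df = pd.DataFrame(matched_rows)
        omst_df.to_csv(omst_dir / "omst_metrics.csv", index=False)
        matched_df.to_csv(omst_dir / "matched_metrics.csv", index=False)
        pd.DataFrame(trace_rows).to_csv(omst_dir / "gce_trace.csv", index=False)
        present_metrics = tuple(m_ for m_ in cfg.metric_set)
        table2 = compare_omst_vs_matched(
            omst_df, matched_df, metrics=present_metrics,
            n_permutations=cfg.n_permutations, seed=cfg.seed,
        )
        table2.to_csv(omst_dir / "omst_vs_threshold.csv", index=False)
        # OMST edge-probability contrast
        for measure in cfg.measures:
            eps = [edge_probabilities(omst_graphs[measure], labels, measure, "omst")]
            scale_across_thresholds(eps)
            edgeprob_long_frame(eps).to_csv(
                ep_dir / f"edge_probabilities_omst_{measure}.csv", index=False
            )
        logger.info("omst done (%.1f s)", time.time() - t0)

        # -- statistics -----------------------------------------------------
        stage = "stats"
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        reg_rows = []
        for measure in cfg.measures:
            for metric in cfg.metric_set:
                try:
                    fit = fit_density_regression(sweep_df, metric, x="q",
                                                 measure=measure)
                except ValueError:
                    continue
                reg_rows.append(
                    {"measure": measure, "metric": metric,
                     "Intercept": fit.intercept,
                     "Density value (Coef)": fit.slope,
                     "Adj.R.squared": fit.adj_r_squared,
                     "p_slope": fit.p_slope, "n": fit.n}
                )
        pd.DataFrame(reg_rows).to_csv(stats_dir / "regression_table.csv", index=False)
        if groups_present and len(groups_present) == 2:
            prof_frames = []
            for measure in cfg.measures:
                for metric in cfg.metric_set:
                    prof = group_effect_profile(
                        sweep_df, metric, measure=measure,
                        n_permutations=cfg.n_permutations,
                        seed=cfg.seed, alpha=cfg.alpha,
                    )
                    prof.insert(0, "metric", metric)
                    prof.insert(0, "measure", measure)
                    prof_frames.append(prof)
            pd.concat(prof_frames).to_csv(stats_dir / "group_profile.csv", index=False)
    except RuntimeError:
        logger.exception("pipeline aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = {
        "package": "fcsweep",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
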