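"""End-to-end orchestration: cohort -> CSD -> CWT -> ERSP/ITC -> dwPLI graphs
-> cluster and permutation statistics, with deterministic seeding and plain
TSV/JSON outputs.

Per-subject time-frequency decompositions are processed in trial chunks so the
pipeline's memory footprint stays bounded at high channel counts; only the
reduced quantities (maps in the statistics domain, band association matrices,
graph metrics) are retained.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster_stats import ClusterTestConfig, independent_cluster_test, paired_cluster_test, permutation_mean_test
from .connectivity import dwpli_from_coeffs, global_efficiency, local_efficiency, node_strength, proportional_threshold, BandConnectivity
from .csd import build_spline_operator, surface_laplacian
from .epochs import EpochedEEG
from .ersp_itc import DEFAULT_BASELINE_MS
from .layout import build_adjacency, default_biosemi128
from .synthetic import SyntheticCohortConfig, generate_cohort
from .timefreq import make_frequency_grid, morlet_cwt


@dataclass
class PipelineConfig:
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    seed: int = 0
    # time-frequency
    grid_fmin: float = 0.32
    grid_fmax: float = 73.0
    grid_ratio: float = 1.1
    wavelet_bandwidth: float = 1.0
    wavelet_center_freq: float = 1.0
    # ERSP/ITC
    baseline_ms: tuple = DEFAULT_BASELINE_MS
    analysis_window_ms: tuple = (-150.0, 150.0)
    # CSD
    apply_csd: bool = True
    csd_m: int = 4
    csd_lambda: float = 1e-5
    csd_max_degree: int = 10
    # connectivity
    connectivity_bands: tuple = ("delta", "theta", "alpha", "beta")
    connectivity_window_ms: tuple = (-150.0, 150.0)
    proportional_keep: float = 0.02
    # statistics
    cluster_alpha: float = 0.001
    n_permutations: int = 10000
    final_alpha: float = 0.05
    stats_freq_range: tuple = (0.5, 70.0)
    distance_threshold: float = 0.4
    # implementation
    trial_chunk: int = 16

    def validate(self) -> None:
        ep0, ep1 = self.cohort.window_ms
        for name, (w0, w1) in (("baseline", self.baseline_ms),
                               ("analysis window", self.analysis_window_ms),
                               ("connectivity window", self.connectivity_window_ms)):
            if w0 < ep0 or w1 > ep1:
                raise ValueError(f"pipeline config: {name} {w0, w1} ms lies outside the epoch {self.cohort.window_ms}")
        if not (0 < self.proportional_keep <= 1):
            raise ValueError("pipeline config: proportional_keep out of (0, 1]")
        if self.grid_fmax >= self.cohort.sfreq / 2:
            raise ValueError("pipeline config: grid_fmax at or above Nyquist")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SubjectResult:
    subject: str
    group: str
    itc_win: np.ndarray       # (c, f_domain, t_win)
    itc_base: np.ndarray      # (c, f_domain) baseline-window mean ITC
    ersp_win: np.ndarray
    connectivity: dict        # band -> BandConnectivity
    metrics: pd.DataFrame     # tidy per-channel metrics


def analyze_subject(ep: EpochedEEG, cfg: PipelineConfig, grid, csd_op=None,
                    domain_fidx=None) -> SubjectResult:
    """Reduce one subject's epochs to statistics-domain maps and band graphs."""
    if cfg.apply_csd and csd_op is not None and not ep.is_csd:
        ep = surface_laplacian(ep, csd_op)
    if domain_fidx is None:
        lo, hi = cfg.stats_freq_range
        domain_fidx = np.flatnonzero((grid.freqs >= lo) & (grid.freqs <= hi))
    conn_fidx = np.unique(np.concatenate([grid.band_indices(b) for b in cfg.connectivity_bands]))

    n = ep.n_trials
    phasor_sum = None
    gain_sum = None
    gain_cnt = None
    F_win_parts = []
    win_mask = base_mask = None
    for c0 in range(0, n, cfg.trial_chunk):
        chunk = ep.copy_with(data=ep.data[c0:c0 + cfg.trial_chunk], metadata=None)
        tf = morlet_cwt(chunk, grid, cfg.wavelet_bandwidth, cfg.wavelet_center_freq,
                        dtype=np.complex64)
        if win_mask is None:
            win_mask = tf.time_mask(cfg.analysis_window_ms)
            base_mask = tf.time_mask(cfg.baseline_ms)
            conn_mask = tf.time_mask(cfg.connectivity_window_ms)
        power = np.abs(tf.coeffs) ** 2
        base = power[..., base_mask].mean(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            gains = power / base[..., None]
        finite = np.isfinite(gains)
        gains[~finite] = 0.0
        phasors = tf.coeffs / np.maximum(np.abs(tf.coeffs), 1e-300)
        if phasor_sum is None:
            phasor_sum = phasors.sum(axis=0)
            gain_sum = gains.sum(axis=0)
            gain_cnt = finite.sum(axis=0).astype(np.int64)
        else:
            phasor_sum += phasors.sum(axis=0)
            gain_sum += gains.sum(axis=0)
            gain_cnt += finite.sum(axis=0)
        F_win_parts.append(tf.coeffs[:, :, conn_fidx][:, :, :, conn_mask])

    itc_map = np.abs(phasor_sum) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        ersp_map = 10.0 * np.log10(gain_sum / np.maximum(gain_cnt, 1))

    itc_win = itc_map[:, domain_fidx][:, :, win_mask]
    itc_base = itc_map[:, domain_fidx][:, :, base_mask].mean(axis=-1)
    ersp_win = ersp_map[:, domain_fidx][:, :, win_mask]

    F_win = np.concatenate(F_win_parts, axis=0)
    connectivity, metric_rows = {}, []
    meta = ep.metadata
    subject = str(meta["subject"].iloc[0]) if meta is not None and "subject" in meta else "?"
    group = str(meta["group"].iloc[0]) if meta is not None and "group" in meta else "?"
    for band in cfg.connectivity_bands:
        bidx = np.searchsorted(conn_fidx, grid.band_indices(band))
        F = F_win[:, :, bidx].reshape(F_win.shape[0], F_win.shape[1], -1)
        W, W_raw = dwpli_from_coeffs(F, clamp_negative=True)
        conn = BandConnectivity(W=W, band=band, window_ms=tuple(cfg.connectivity_window_ms),
                                n_trials=n, ch_names=list(ep.ch_names), W_raw=W_raw)
        connectivity[band] = conn
        ns = node_strength(conn)
        le = local_efficiency(conn)
        ge = global_efficiency(conn)
        for ci, ch in enumerate(ep.ch_names):
            metric_rows.append((subject, group, band, ch, "node_strength", ns[ci]))
            metric_rows.append((subject, group, band, ch, "local_efficiency", le[ci]))
        metric_rows.append((subject, group, band, "GLOBAL", "global_efficiency", ge))
    metrics = pd.DataFrame(metric_rows, columns=["subject", "group", "band", "channel",
                                                 "metric", "value"])
    return SubjectResult(subject=subject, group=group, itc_win=itc_win, itc_base=itc_base,
                         ersp_win=ersp_win, connectivity=connectivity, metrics=metrics)


def run_pipeline(cfg: PipelineConfig, outdir=None, cohort=None) -> dict:
    """Run the full analysis; returns a result bundle and optionally writes
    TSV/JSON outputs under ``outdir``.  Deterministic given (config, seed)."""
    cfg.validate()
    grid = make_frequency_grid(cfg.grid_fmin, cfg.grid_fmax, cfg.grid_ratio)
    if cohort is None:
        cohort = generate_cohort(cfg.cohort, master_seed=cfg.seed)

    layout = default_biosemi128().subset(cfg.cohort.ch_names)
    adjacency = build_adjacency(layout, distance_threshold=cfg.distance_threshold)
    csd_op = build_spline_operator(layout, m=cfg.csd_m, lam=cfg.csd_lambda,
                                   max_degree=cfg.csd_max_degree) if cfg.apply_csd else None

    lo, hi = cfg.stats_freq_range
    domain_fidx = np.flatnonzero((grid.freqs >= lo) & (grid.freqs <= hi))

    results = {name: [] for name in cohort.groups}
    for name, subjects in cohort.groups.items():
        for ep in subjects:
            results[name].append(analyze_subject(ep, cfg, grid, csd_op, domain_fidx))

    group_names = list(cohort.groups)
    stacks = {}
    for name in group_names:
        rs = results[name]
        stacks[name] = {
            "itc_win": np.stack([r.itc_win for r in rs]),
            "itc_base": np.stack([np.repeat(r.itc_base[:, :, None], r.itc_win.shape[2], axis=2)
                                  for r in rs]),
            "ersp_win": np.stack([r.ersp_win for r in rs]),
        }

    ccfg = ClusterTestConfig(cluster_alpha=cfg.cluster_alpha, n_permutations=cfg.n_permutations,
                             alpha=cfg.final_alpha, adjacency=adjacency, seed=cfg.seed,
                             time_window_ms=tuple(cfg.analysis_window_ms),
                             freq_range_hz=tuple(cfg.stats_freq_range))
    cluster_results = {}
    for name in group_names:
        cluster_results[f"within_{name}_itc"] = paired_cluster_test(
            stacks[name]["itc_win"], stacks[name]["itc_base"], ccfg)
        cluster_results[f"within_{name}_ersp"] = paired_cluster_test(
            stacks[name]["ersp_win"], np.zeros_like(stacks[name]["ersp_win"]), ccfg)
    if len(group_names) == 2:
        ga, gb = group_names
        cluster_results[f"between_{ga}_vs_{gb}_itc"] = independent_cluster_test(
            stacks[ga]["itc_win"], stacks[gb]["itc_win"], ccfg)
        cluster_results[f"between_{ga}_vs_{gb}_ersp"] = independent_cluster_test(
            stacks[ga]["ersp_win"], stacks[gb]["ersp_win"], ccfg)

    metrics = pd.concat([r.metrics for rs in results.values() for r in rs], ignore_index=True)
    metric_tests = []
    if len(group_names) == 2:
        ga, gb = group_names
        for band in cfg.connectivity_bands:
            for metric, agg in (("global_efficiency", "value"),
                                ("node_strength", "mean"), ("local_efficiency", "mean")):
                per_subj = (metrics[(metrics.band == band) & (metrics.metric == metric)]
                            .groupby(["group", "subject"])["value"].mean())
                res = permutation_mean_test(per_subj[ga].values, per_subj[gb].values,
                                            n_perm=min(cfg.n_permutations, 10000), seed=cfg.seed)
                metric_tests.append((band, metric, float(per_subj[ga].mean()),
                                     float(per_subj[gb].mean()), res.observed, res.p))
    metric_tests = pd.DataFrame(metric_tests, columns=[
        "band", "metric", f"mean_{group_names[0]}", f"mean_{group_names[-1]}",
        "abs_mean_difference", "p_value"])

    thresholded = {
        name: {band: proportional_threshold(results[name][0].connectivity[band],
                                            cfg.proportional_keep)
               for band in cfg.connectivity_bands}
        for name in group_names
    }

    bundle = {
        "config": cfg,
        "grid": grid,
        "adjacency": adjacency,
        "ground_truth": cohort.ground_truth,
        "domain_freqs": grid.freqs[domain_fidx],
        "subject_results": results,
        "cluster_results": cluster_results,
        "metrics": metrics,
        "metric_tests": metric_tests,
        "thresholded_example": thresholded,
        "manifest": {
            "package_version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_subjects": {name: len(v) for name, v in cohort.groups.items()},
        },
    }
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def cluster_summary_table(bundle: dict) -> pd.DataFrame:
    rows = []
    for name, res in bundle["cluster_results"].items():
        for ci, c in enumerate(res.clusters):
            rows.append((name, ci, c.sign, c.mass, c.p, len(c.cells),
                         len(np.unique(c.cells[:, 0]))))
    return pd.DataFrame(rows, columns=["contrast", "cluster", "sign", "mass", "p",
                                       "n_cells", "n_channels"]).sort_values(
        ["contrast", "p"]).reset_index(drop=True)


def write_bundle(bundle: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["metrics"].to_csv(outdir / "graph_metrics.tsv", sep="\t", index=False)
    bundle["metric_tests"].to_csv(outdir / "graph_metric_tests.tsv", sep="\t", index=False)
    cluster_summary_table(bundle).to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)
    summary = {
        "manifest": bundle["manifest"],
        "ground_truth": {
            "itc": bundle["ground_truth"].itc,
            "ersp_db": bundle["ground_truth"].ersp_db,
        },
        "significant_clusters": {
            name: [{"sign": c.sign, "mass": c.mass, "p": c.p, "n_cells": int(len(c.cells))}
                   for c in res.significant()]
            for name, res in bundle["cluster_results"].items()
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def report(bundle: dict) -> str:
    """Human-readable markdown summary of a result bundle."""
    lines = ["# Motor-execution EEG analysis report", ""]
    man = bundle["manifest"]
    lines += [f"Package version {man['package_version']}, seed {man['seed']}, "
              f"config hash `{man['config_hash']}`.",
              f"Subjects: {man['n_subjects']}", ""]
    lines.append("## Cluster tests")
    any_sig = False
    for name, res in bundle["cluster_results"].items():
        sig = res.significant()
        if not sig:
            continue
        any_sig = True
        for c in sig:
            chans = np.unique(c.cells[:, 0])
            lines.append(f"- {name}: {'positive' if c.sign > 0 else 'negative'} cluster, "
                         f"mass {c.mass:.1f}, p = {c.p:.4g}, {len(c.cells)} cells over "
                         f"{len(chans)} channels")
    if not any_sig:
        lines.append("no significant clusters")
    lines += ["", "## Graph-metric permutation tests", ""]
    mt = bundle["metric_tests"]
    if len(mt):
        lines.append(mt.to_string(index=False))
    else:
        lines.append("no between-group metric tests (need exactly 2 groups)")
    return "\n".join(lines) + "\n"
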