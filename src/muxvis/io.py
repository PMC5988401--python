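"""File formats, run configuration and the end-to-end pipeline.

The pipeline consumes per-subject ROI time-series tables (CSV/TSV, rows =
time points, columns = ROIs), a two-column ROI -> network map and a
participants table with group and covariates.  Per subject it builds the
multiplex visibility graph, the interlayer-MI matrix and the per-network
<MI> summary; across subjects it compares the group-wise <MI> distributions
(Harrell-Davis medians with Bayesian-bootstrap intervals, pairwise KS,
shift function, Holm-corrected covariate-adjusted group tests) and ranks
networks by group separation.  Every output embeds the configuration hash
and seeds, and a re-run with an identical configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import multiplex as mx
from . import stats as rs
from .synthetic import CohortSpec, generate_cohort

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "read_network_map",
    "write_network_map",
    "write_cohort",
    "cohort_network_mi",
    "group_ks_by_network",
    "analyze_groups",
    "run_pipeline",
]

log = logging.getLogger("muxvis")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on; hashable for provenance."""

    input_dir: str = "."
    output_dir: str = "out"
    participants: str = "participants.csv"  # relative to input_dir
    network_map: str = "network_map.csv"
    method: str = "natural"  # natural | horizontal
    log_base: float | None = None  # None = natural log (nats)
    louvain_runs: int = 100
    louvain_resolution: float = 1.0
    n_boot: int = 2000
    n_draws: int = 2000
    hdi_level: float = 0.95
    alpha: float = 0.05
    seed: int = 0
    force_orientation: bool = False
    transpose: bool = False

    def __post_init__(self):
        if self.method not in ("natural", "horizontal"):
            raise ValueError(f"unknown method {self.method!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def units(self) -> str:
        return "nats" if self.log_base is None else f"log base {self.log_base:g}"


# ---------------------------------------------------------------- formats

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_timeseries(path, force_orientation: bool = False,
                    transpose: bool = False):
    """Read a time-series table: rows = time points, header = ROI labels.

    Returns ``(matrix T x M, roi_labels)``.  A square table is rejected as
    ambiguous unless ``force_orientation`` is set; ``transpose`` reads the
    table as ROIs-in-rows (index column = ROI label) and transposes it.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0 if transpose else None)
    if transpose:
        df = df.T
        labels = [str(c) for c in df.columns]
    else:
        # pandas silently renames duplicate header fields; check the raw line
        with open(path) as fh:
            labels = [c.strip() for c in fh.readline().rstrip("\n").split(sep)]
    if len(set(labels)) != len(labels):
        dup = sorted({c for c in labels if labels.count(c) > 1})
        raise ValueError(f"duplicate ROI labels in {path}: {dup}")
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] == mat.shape[1] and not force_orientation:
        raise ValueError(
            f"{path}: square {mat.shape[0]}x{mat.shape[1]} table is ambiguous; "
            "pass force_orientation=True to read rows as time points")
    bad = np.argwhere(~np.isfinite(mat))
    if bad.size:
        t, j = bad[0]
        raise ValueError(f"{path}: non-finite value at time row {t}, "
                         f"ROI column {labels[j]!r}")
    return mat, labels


def write_timeseries(matrix, roi_labels, path) -> None:
    pd.DataFrame(np.asarray(matrix, dtype=float),
                 columns=list(roi_labels)).to_csv(path, index=False,
                                                  sep=_sep_for(path))


def read_network_map(path, roi_labels=None) -> dict[str, str]:
    """Two-column CSV (roi_label, network_name) -> total ROI -> network map.

    When ``roi_labels`` is given the map must cover exactly those ROIs;
    missing or unknown ROIs and empty network names are errors, as are
    duplicated ROI rows with conflicting networks.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (roi, network)")
    rois = df.iloc[:, 0].astype(str)
    nets = df.iloc[:, 1]
    mapping: dict[str, str] = {}
    for roi, net in zip(rois, nets):
        if pd.isna(net) or str(net).strip() == "":
            raise ValueError(f"{path}: empty network name for ROI {roi!r}")
        net = str(net)
        if roi in mapping and mapping[roi] != net:
            raise ValueError(f"{path}: ROI {roi!r} mapped to both "
                             f"{mapping[roi]!r} and {net!r}")
        mapping[roi] = net
    if roi_labels is not None:
        missing = [r for r in roi_labels if r not in mapping]
        if missing:
            raise ValueError(f"{path}: network map missing ROIs {missing}")
        unknown = [r for r in mapping if r not in set(map(str, roi_labels))]
        if unknown:
            raise ValueError(f"{path}: network map lists unknown ROIs {unknown}")
    return mapping


def write_network_map(mapping: dict[str, str], path) -> None:
    pd.DataFrame({"roi": list(mapping), "network": list(mapping.values())
                  }).to_csv(path, index=False)


def write_cohort(spec: CohortSpec, out_dir) -> Path:
    """Materialize a synthetic cohort in the layout the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, participants, roi_labels, networks = generate_cohort(spec)
    for sid, mat in subjects.items():
        write_timeseries(mat, roi_labels, out / f"{sid}.csv")
    participants.to_csv(out / "participants.csv", index=False)
    write_network_map(dict(zip(roi_labels, networks)), out / "network_map.csv")
    return out


# ------------------------------------------------------- group analysis

def cohort_network_mi(subjects: dict[str, np.ndarray], network_labels,
                      method: str = "natural",
                      base: float | None = None) -> pd.DataFrame:
    """Per-subject per-network <MI> table (rows = subjects, cols = networks)."""
    rows = {sid: mx.subject_network_mi(mat, network_labels, method, base)
            for sid, mat in subjects.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def group_ks_by_network(mi_df: pd.DataFrame,
                        participants: pd.DataFrame) -> pd.Series:
    """Max pairwise-group KS statistic of the <MI> distribution, per network,
    sorted descending (the ranking the pipeline reports)."""
    groups = participants.set_index("subject_id").loc[mi_df.index, "group"]
    names = groups.unique()
    out = {}
    for net in mi_df.columns:
        ks = [rs.ks_statistic(mi_df.loc[groups.to_numpy() == a, net],
                              mi_df.loc[groups.to_numpy() == b, net])
              for i, a in enumerate(names) for b in names[i + 1:]]
        out[net] = max(ks) if ks else 0.0
    return pd.Series(out, name="max_group_ks").sort_values(ascending=False)


def analyze_groups(mi_df: pd.DataFrame, participants: pd.DataFrame,
                   config: RunConfig) -> dict:
    """Across-subject group comparison of per-network <MI> distributions."""
    part = participants.set_index("subject_id").loc[mi_df.index]
    groups = part["group"]
    names = list(dict.fromkeys(groups))
    covs = part[[c for c in ("age", "fd") if c in part.columns]]
    rng_seed = np.random.SeedSequence(config.seed).generate_state(2)
    report: dict = {"networks": {}, "units": config.units()}
    raw_p = {}
    for net in mi_df.columns:
        entry: dict = {"groups": {}}
        for g in names:
            vals = mi_df.loc[groups.to_numpy() == g, net].to_numpy()
            if vals.size >= 2:
                med, (lo, hi) = rs.bayes_boot_hdi(
                    vals, level=config.hdi_level, n_draws=config.n_draws,
                    seed=int(rng_seed[0]))
                entry["groups"][g] = {"n": int(vals.size),
                                      "hd_median": med,
                                      "hdi": [lo, hi]}
        pair_ks = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                xa = mi_df.loc[groups.to_numpy() == a, net]
                xb = mi_df.loc[groups.to_numpy() == b, net]
                if len(xa) >= 1 and len(xb) >= 1:
                    pair_ks[f"{a}|{b}"] = rs.ks_statistic(xa, xb)
        entry["pairwise_ks"] = pair_ks
        if len(names) >= 2:
            try:
                raw_p[net] = rs.group_covariate_test(
                    mi_df[net].to_numpy(), groups.to_numpy(),
                    covs if covs.shape[1] else None)
            except ValueError:
                pass
        a, b = names[0], names[-1] if len(names) > 1 else names[0]
        xa = mi_df.loc[groups.to_numpy() == a, net].to_numpy()
        xb = mi_df.loc[groups.to_numpy() == b, net].to_numpy()
        if a != b and xa.size >= 10 and xb.size >= 10:
            shift = rs.shift_function(xa, xb, n_boot=config.n_boot,
                                      seed=int(rng_seed[1]))
            entry["shift_function"] = {
                "groups": [a, b],
                **{k: v.tolist() for k, v in
                   (("quantiles", shift.quantiles),
                    ("difference", shift.differences),
                    ("lower", shift.lower), ("upper", shift.upper))},
            }
        report["networks"][net] = entry
    if raw_p:
        nets = list(raw_p)
        adj = rs.holm_adjust([raw_p[n] for n in nets])
        for n, p_raw, p_adj in zip(nets, (raw_p[n] for n in nets), adj):
            report["networks"][n]["group_test"] = {
                "p_raw": float(p_raw), "p_holm": float(p_adj),
                "covariates": list(covs.columns)}
    ranking = group_ks_by_network(mi_df, participants.reset_index()
                                  if "subject_id" not in participants.columns
                                  else participants)
    report["network_ranking_by_ks"] = {k: float(v) for k, v in ranking.items()}
    return report


# ---------------------------------------------------------------- pipeline

def _stage(name: str, t0: float, **shapes) -> None:
    info = " ".join(f"{k}={v}" for k, v in shapes.items())
    log.info("stage=%s %s elapsed=%.2fs", name, info, time.perf_counter() - t0)


def run_pipeline(config: RunConfig) -> dict:
    """End-to-end analysis: per-subject MI artifacts plus a group report.

    Writes, under ``config.output_dir``: per-subject MI matrices (CSV +
    JSON sidecar), per-subject summary JSONs with per-network <MI>, and
    ``group_report.json``.  Returns the group report.  With a single
    subject the group statistics are skipped with an explicit notice.
    """
    t0 = time.perf_counter()
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config": asdict(config), "config_hash": config.config_hash(),
                  "seed": config.seed}

    participants = pd.read_csv(in_dir / config.participants)
    if "subject_id" not in participants.columns:
        raise ValueError("participants table needs a subject_id column")
    sids = participants["subject_id"].astype(str).tolist()
    _stage("read_participants", t0, n_subjects=len(sids))

    mi_rows: dict[str, dict[str, float]] = {}
    net_labels = roi_labels = None
    for sid in sids:
        ts_path = in_dir / f"{sid}.csv"
        if not ts_path.exists():
            ts_path = in_dir / f"{sid}.tsv"
        try:
            mat, roi_labels = read_timeseries(
                ts_path, config.force_orientation, config.transpose)
            net_map = read_network_map(in_dir / config.network_map, roi_labels)
            net_labels = [net_map[r] for r in roi_labels]
            mvg = mx.build_multiplex(mat, config.method, roi_labels, net_labels)
            mim = mx.mi_matrix(mvg, base=config.log_base)
        except Exception as err:
            raise RuntimeError(f"[subject {sid}] {err}") from err
        mx.write_mi_matrix(mim, out_dir / f"{sid}_mi.csv",
                           out_dir / f"{sid}_mi.json", method=config.method,
                           n_nodes=mvg.n_nodes, extra=provenance)
        per_net = {}
        for net in dict.fromkeys(net_labels):
            if net_labels.count(net) >= 2:
                per_net[net] = mx.network_avg_mi(mim, net)
        mi_rows[sid] = per_net
        with open(out_dir / f"{sid}_summary.json", "w") as fh:
            json.dump({"subject_id": sid, "method": config.method,
                       "units": config.units(), "network_mi": per_net,
                       **provenance}, fh, indent=2)
    mi_df = pd.DataFrame.from_dict(mi_rows, orient="index")
    mi_df.index.name = "subject_id"
    mi_df.to_csv(out_dir / "network_mi.csv")
    _stage("subject_mi", t0, n_subjects=len(sids),
           n_networks=mi_df.shape[1])

    if len(sids) < 2 or participants["group"].nunique() < 2:
        report = {"notice": "group statistics skipped: need at least two "
                            "subjects in at least two groups",
                  "n_subjects": len(sids), **provenance}
    else:
        report = analyze_groups(mi_df, participants, config)
        report.update(provenance)
    with open(out_dir / "group_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _stage("group_report", t0, n_subjects=len(sids))
    return report
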