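"""Synthetic band-limited, network-structured multivariate signals.

Emulates preprocessed resting-state ROI time series: each ROI belongs to one
labelled network, ROIs of a network share a latent signal with tunable
coupling, and everything is band-pass filtered to the conventional
resting-state band (0.01-0.08 Hz at TR = 2 s) and standardized.  For ROI i
in network g,

    x_i = sqrt(rho_g) * z_g + sqrt(1 - rho_g) * eps_i,

with z_g a shared network latent, eps_i independent Gaussian noise and
rho_g in [0, 1] the within-network coupling, so rho is a direct ground
truth for how much interlayer structure the downstream mutual-information
analysis should recover (rho = 0: independent ROIs; rho = 1: identical).

Cohorts add a subject grouping (default: one large control group and three
smaller clinical groups, 121/50/49/40 subjects) with per-group coupling and
synthetic age / framewise-displacement covariates whose group confounding
is configurable, for exercising covariate-adjusted tests.  All randomness
descends from one master seed through ``numpy.random.SeedSequence`` spawns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

__all__ = ["CohortSpec", "default_network_map", "generate_subject",
           "generate_cohort"]

#: samples discarded at each end after zero-phase filtering (edge effects)
EDGE_TRIM = 8


def default_network_map(m: int, n_networks: int | None = None) -> dict[str, str]:
    """Assign m ROI labels in contiguous blocks to labelled networks.

    By default the number of networks is ``min(9, m // 3)`` (at least one),
    so the desk-scale default m = 27 yields nine 3-ROI networks named
    net0..net8; ROI labels are roi0..roi{m-1}.
    """
    if n_networks is None:
        n_networks = min(9, max(1, m // 3))
    per = int(np.ceil(m / n_networks))
    return {f"roi{i}": f"net{min(i // per, n_networks - 1)}" for i in range(m)}


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth description of a synthetic multi-group cohort.

    ``coupling`` maps group -> within-network coupling rho, either one
    scalar for all networks or a dict network -> rho.  ``T`` counts raw
    samples before edge trimming: subjects come out with T - 16 time
    points.  ``age_shift`` / ``fd_shift`` add a per-group offset to the
    covariates to emulate confounding.
    """

    n_subjects: dict[str, int] = field(default_factory=lambda: {
        "control": 121, "schizophrenia": 50, "bipolar": 49, "adhd": 40})
    M: int = 27
    T: int = 150
    dt: float = 2.0
    passband: tuple[float, float] = (0.01, 0.08)
    network_map: dict[str, str] | None = None
    coupling: dict[str, float | dict[str, float]] = field(
        default_factory=lambda: {
            "control": 0.5, "schizophrenia": 0.5, "bipolar": 0.5, "adhd": 0.5})
    noise_sd: float = 1.0
    age_shift: dict[str, float] | None = None
    fd_shift: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        low, high = self.passband
        if not 0.0 < low < high < 0.5 / self.dt:
            raise ValueError("passband must satisfy 0 < low < high < Nyquist")
        if self.T < 32:
            raise ValueError("T must be >= 32")
        if any(n < 1 for n in self.n_subjects.values()):
            raise ValueError("empty group in n_subjects")
        for g, rho in self.coupling.items():
            vals = rho.values() if isinstance(rho, dict) else [rho]
            if any(not 0.0 <= r <= 1.0 for r in vals):
                raise ValueError(f"coupling for group {g!r} outside [0, 1]")

    def resolved_network_map(self) -> dict[str, str]:
        return (dict(self.network_map) if self.network_map is not None
                else default_network_map(self.M))

    def rho_for(self, group: str, network: str) -> float:
        rho = self.coupling[group]
        return float(rho[network]) if isinstance(rho, dict) else float(rho)


def _bandpass_sos(spec: CohortSpec):
    low, high = spec.passband
    nyq = 0.5 / spec.dt
    return spsig.butter(4, [low / nyq, high / nyq], btype="bandpass",
                        output="sos")


def generate_subject(spec: CohortSpec, subject_seed, group: str | None = None):
    """One subject's (T - 16) x M signal matrix plus ROI/network labels.

    ``subject_seed`` may be an int or a ``SeedSequence``.  Deterministic:
    the same spec and seed reproduce the output bit for bit.
    """
    group = group if group is not None else next(iter(spec.n_subjects))
    rng = np.random.default_rng(subject_seed)
    net_map = spec.resolved_network_map()
    roi_labels = list(net_map)
    if len(roi_labels) != spec.M:
        raise ValueError("network_map must cover exactly M ROIs")
    networks = [net_map[r] for r in roi_labels]
    latents = {g: rng.standard_normal(spec.T)
               for g in dict.fromkeys(networks)}
    x = np.empty((spec.T, spec.M))
    for j, net in enumerate(networks):
        rho = spec.rho_for(group, net)
        eps = rng.standard_normal(spec.T) * spec.noise_sd
        x[:, j] = np.sqrt(rho) * latents[net] + np.sqrt(1.0 - rho) * eps
    x = spsig.sosfiltfilt(_bandpass_sos(spec), x, axis=0)
    x = x[EDGE_TRIM:-EDGE_TRIM]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return x, roi_labels, networks


def generate_cohort(spec: CohortSpec):
    """Full cohort: subject matrices, participants table, labels.

    Returns ``(subjects, participants, roi_labels, network_labels)`` where
    ``subjects`` maps subject id -> (T - 16) x M matrix and
    ``participants`` is a DataFrame with subject_id, group, age and
    framewise displacement (fd) covariates.
    """
    master = np.random.SeedSequence(spec.seed)
    n_total = sum(spec.n_subjects.values())
    seeds = master.spawn(n_total + 1)
    cov_rng = np.random.default_rng(seeds[-1])
    subjects: dict[str, np.ndarray] = {}
    rows = []
    i = 0
    roi_labels = networks = None
    for group, n in spec.n_subjects.items():
        for k in range(n):
            sid = f"sub-{group}-{k:03d}"
            x, roi_labels, networks = generate_subject(spec, seeds[i], group)
            subjects[sid] = x
            age = float(np.clip(cov_rng.normal(45.0, 12.0), 18.0, 80.0))
            fd = float(cov_rng.lognormal(mean=-2.0, sigma=0.5))
            if spec.age_shift:
                age += spec.age_shift.get(group, 0.0)
            if spec.fd_shift:
                fd += spec.fd_shift.get(group, 0.0)
            rows.append({"subject_id": sid, "group": group,
                         "age": age, "fd": fd})
            i += 1
    participants = pd.DataFrame(rows)
    return subjects, participants, roi_labels, networks
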