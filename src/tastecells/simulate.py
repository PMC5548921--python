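"""Synthetic data with known ground truth for every pipeline stage.

Generates (a) ratiometric calcium traces with the variable sampling schedule
used at the rig (2 s during stimulus, 4-8 s during recovery, 30-60 s during
baseline), (b) negative-binomial gene x cell count matrices with per-cell
depth variation, optional dropout, and marker genes at taste-cell effect
sizes (|log2FC| ~ 5-15), and (c) gene-set annotations with planted enriched
terms. Each generator records the truth it simulated so detectors and tests
can score themselves against it.

All randomness flows through ``numpy.random.default_rng(seed)`` held inside
each call; there is no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .calcium import CalciumTrace, DetectorConfig, StimulusEvent

__all__ = [
    "SchedulePhase",
    "TraceSimSpec",
    "CountSimSpec",
    "TruthTable",
    "simulate_trace",
    "simulate_cohort",
    "simulate_counts",
    "simulate_annotation",
    "load_table1_markers",
]

_PHASES = ("baseline", "stimulus", "recovery")


def load_table1_markers() -> pd.DataFrame:
    """Packaged marker-gene fixture: taste cell-type markers with the
    published group-average counts and log2 fold changes (type III over
    Tas1r3+ orientation)."""
    with resources.files("tastecells.data").joinpath("table1_markers.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass(frozen=True)
class SchedulePhase:
    phase: str  # baseline | stimulus | recovery
    interval_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.phase not in _PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.interval_s <= 0 or self.duration_s <= 0:
            raise ValueError("interval and duration must be positive")


# Idle periods between presentations are sampled sparsely (30-60 s); the
# capture rate ramps back up ahead of a presentation so the 120-s baseline
# window that feeds the detector's SD estimate holds ~12 samples.
_DEFAULT_SCHEDULE = (
    SchedulePhase("baseline", 30.0, 60.0),
    SchedulePhase("baseline", 10.0, 120.0),
    SchedulePhase("stimulus", 2.0, 40.0),
    SchedulePhase("recovery", 6.0, 180.0),
)


@dataclass(frozen=True)
class TraceSimSpec:
    """Parameters of one simulated fura-2 trace.

    The noiseless signal is ``baseline_level`` before stimulus onset, steps to
    ``baseline_level + amplitude`` for ``plateau_s`` seconds, then declines
    linearly at ``recovery_slope`` AU/s back to baseline. The amplitude is
    ``response_amplitude_sd * noise_sd`` (multiples of the noise SD) unless
    ``response_amplitude_au`` pins it in AU directly (needed e.g. for
    noiseless traces). I.i.d. Gaussian noise of SD ``noise_sd`` is added at
    every sample.
    """

    baseline_level: float = 1.0
    noise_sd: float = 0.01
    stim_onset_s: float = 180.0
    response_amplitude_sd: float = 40.0
    plateau_s: float = 30.0
    recovery_slope: float = 0.002
    schedule: tuple[SchedulePhase, ...] = _DEFAULT_SCHEDULE
    seed: int = 0
    response_amplitude_au: float | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.response_amplitude_sd < 0:
            raise ValueError("noise_sd and response_amplitude_sd must be >= 0")
        if self.recovery_slope < 0:
            raise ValueError("recovery_slope must be >= 0")
        baseline_dur = sum(p.duration_s for p in self.schedule if p.phase == "baseline")
        if baseline_dur < 120.0:
            raise ValueError(
                f"baseline phase lasts {baseline_dur:g} s; need >= 120 s for baseline statistics"
            )
        pre_stim = 0.0
        for p in self.schedule:
            if p.phase == "stimulus":
                break
            pre_stim += p.duration_s
        if not math.isclose(pre_stim, self.stim_onset_s, abs_tol=1e-9):
            raise ValueError(
                f"stim_onset_s={self.stim_onset_s:g} but schedule places stimulus at {pre_stim:g} s"
            )

    @property
    def amplitude_au(self) -> float:
        if self.response_amplitude_au is not None:
            return self.response_amplitude_au
        return self.response_amplitude_sd * self.noise_sd


def _signal(spec: TraceSimSpec, t: np.ndarray) -> np.ndarray:
    amp = spec.amplitude_au
    end_plateau = spec.stim_onset_s + spec.plateau_s
    sig = np.full_like(t, spec.baseline_level, dtype=float)
    on = (t >= spec.stim_onset_s) & (t <= end_plateau)
    sig[on] = spec.baseline_level + amp
    rec = t > end_plateau
    sig[rec] = np.maximum(
        spec.baseline_level,
        spec.baseline_level + amp - spec.recovery_slope * (t[rec] - end_plateau),
    )
    return sig


def simulate_trace(
    spec: TraceSimSpec,
    cell_id: str = "cell",
    detector: DetectorConfig = DetectorConfig(),
) -> tuple[CalciumTrace, bool]:
    """Simulate one trace; returns it with its ground-truth responded flag.

    The truth flag is recorded from the generating parameters, not inferred
    from the noisy samples: the cell is a true responder when its noiseless
    step exceeds the detection threshold (amplitude > k_sd x noise SD) and
    the plateau is at least the minimum run duration.
    """
    rng = np.random.default_rng(spec.seed)
    times: list[float] = []
    t0 = 0.0
    for ph in spec.schedule:
        t = t0 if not times else max(t0, times[-1] + ph.interval_s)
        # sample on the phase's grid up to (and excluding) the phase end
        while t < t0 + ph.duration_s - 1e-9:
            times.append(t)
            t += ph.interval_s
        t0 += ph.duration_s
    tarr = np.asarray(times)
    ratio = _signal(spec, tarr) + rng.normal(0.0, spec.noise_sd, size=tarr.size)
    truth = (
        spec.amplitude_au > detector.k_sd * spec.noise_sd
        and spec.plateau_s >= detector.min_duration_s
    )
    return CalciumTrace(cell_id, tarr, ratio), bool(truth)


def simulate_cohort(
    n_responders: int,
    n_nonresponders: int,
    spec: TraceSimSpec = TraceSimSpec(),
    seed: int = 0,
) -> tuple[list[CalciumTrace], dict[str, list[StimulusEvent]], pd.DataFrame]:
    """Cohort of traces: responders use `spec`, non-responders zero amplitude.

    Returns (traces, events per cell, truth table with per-trace responded
    flag and true amplitude).
    """
    root = np.random.default_rng(seed)
    traces, rows = [], []
    events: dict[str, list[StimulusEvent]] = {}
    stim = StimulusEvent(spec.stim_onset_s, 4.0, "KCl 50 mM")
    for i in range(n_responders + n_nonresponders):
        responder = i < n_responders
        sub = replace(
            spec,
            response_amplitude_sd=spec.response_amplitude_sd if responder else 0.0,
            response_amplitude_au=None,
            seed=int(root.integers(0, 2**31 - 1)),
        )
        cid = f"cell_{i:03d}"
        trace, truth = simulate_trace(sub, cell_id=cid)
        traces.append(trace)
        events[cid] = [stim]
        rows.append(dict(cell_id=cid, responded=truth, true_amplitude_au=sub.amplitude_au))
    return traces, events, pd.DataFrame(rows)


@dataclass(frozen=True)
class CountSimSpec:
    """Parameters for a two-group NB count matrix.

    Defaults mirror the study design this generator emulates: 9 cells in
    group A (Tas1r3+) versus 14 in group B (type III), negative-binomial
    counts with dispersion alpha (Var = mu + alpha mu^2), log-normal gene
    means, per-cell depth factors, and optional Bernoulli dropout. DE genes
    get group-B means shifted by 2**log2fc with magnitudes drawn from
    ``log2fc_range`` (marker-gene scale) and random sign.
    """

    n_genes: int = 5000
    n_cells_a: int = 9
    n_cells_b: int = 14
    mean_log_mu: float = math.log(100.0)
    sd_log_mu: float = 1.5
    de_fraction: float = 0.0
    log2fc_range: tuple[float, float] = (5.0, 15.0)
    de_direction: str = "both"  # "both": random sign; "up": all positive
    dispersion: float = 0.5
    depth_factors: tuple[float, ...] | None = None
    depth_sd_log: float = 0.4
    dropout_prob: float = 0.0
    marker_preset: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        n = self.n_cells_a + self.n_cells_b
        if self.depth_factors is not None and len(self.depth_factors) != n:
            raise ValueError(f"depth_factors must have length {n}")
        if self.marker_preset not in (None, "table1"):
            raise ValueError(f"unknown marker preset {self.marker_preset!r}")
        if self.de_direction not in ("both", "up"):
            raise ValueError("de_direction must be 'both' or 'up'")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a simulated count matrix."""

    genes: pd.DataFrame  # gene_id, true_log2fc, is_de, mu_a, mu_b
    cells: pd.DataFrame  # cell_id, group, depth_factor

    def to_dir(self, path) -> None:
        from pathlib import Path

        p = Path(path)
        p.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(p / "truth_genes.tsv", sep="\t", index=False)
        self.cells.to_csv(p / "truth_cells.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path) -> "TruthTable":
        from pathlib import Path

        p = Path(path)
        return cls(
            genes=pd.read_csv(p / "truth_genes.tsv", sep="\t"),
            cells=pd.read_csv(p / "truth_cells.tsv", sep="\t"),
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2; alpha=0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_counts(spec: CountSimSpec):
    """Simulate a genes x cells count matrix plus its :class:`TruthTable`.

    Counts are NB(depth_c * mu_{g,group}, alpha), then zeroed with
    probability ``dropout_prob``. With ``marker_preset="table1"`` the first
    genes are the packaged taste-cell markers with group-A means set to the
    published Tas1r3+ averages and true log2FC set to the published values,
    so e.g. Plcb2's group-mean ratio is 2**-14.4 before dropout.

    Returns (counts DataFrame with gene index / cell columns,
    cell-group Series, TruthTable).
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_cells_a + spec.n_cells_b
    cell_ids = [f"A_{i+1}" for i in range(spec.n_cells_a)] + [
        f"B_{i+1}" for i in range(spec.n_cells_b)
    ]
    groups = pd.Series(
        ["A"] * spec.n_cells_a + ["B"] * spec.n_cells_b, index=cell_ids, name="group"
    )

    mu_a = rng.lognormal(spec.mean_log_mu, spec.sd_log_mu, size=spec.n_genes)
    log2fc = np.zeros(spec.n_genes)
    is_de = np.zeros(spec.n_genes, dtype=bool)
    gene_ids = np.array([f"gene_{i:05d}" for i in range(spec.n_genes)], dtype=object)

    n_marker = 0
    if spec.marker_preset == "table1":
        markers = load_table1_markers()
        n_marker = len(markers)
        if n_marker > spec.n_genes:
            raise ValueError("n_genes too small for the table1 marker preset")
        gene_ids[:n_marker] = markers["gene_id"].to_numpy()
        mu_a[:n_marker] = markers["avg_count_tas1r3"].to_numpy()
        log2fc[:n_marker] = markers["log2fc"].to_numpy()
        is_de[:n_marker] = True

    n_de = int(round(spec.de_fraction * (spec.n_genes - n_marker)))
    if n_de > 0:
        idx = rng.choice(np.arange(n_marker, spec.n_genes), size=n_de, replace=False)
        mag = rng.uniform(*spec.log2fc_range, size=n_de)
        if spec.de_direction == "up":
            sign = np.ones(n_de)
        else:
            sign = rng.choice([-1.0, 1.0], size=n_de)
        log2fc[idx] = mag * sign
        is_de[idx] = True

    mu_b = mu_a * np.exp2(log2fc)

    if spec.depth_factors is not None:
        depth = np.asarray(spec.depth_factors, dtype=float)
    else:
        depth = rng.lognormal(0.0, spec.depth_sd_log, size=n_cells)
        depth /= np.exp(np.mean(np.log(depth)))  # geometric mean 1

    mu = np.where(
        (groups.to_numpy() == "A")[None, :], mu_a[:, None], mu_b[:, None]
    ) * depth[None, :]
    counts = _nb_draw(rng, mu, spec.dispersion)
    if spec.dropout_prob > 0:
        keep = rng.random(counts.shape) >= spec.dropout_prob
        counts = counts * keep

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=cell_ids)
    truth = TruthTable(
        genes=pd.DataFrame(
            dict(gene_id=gene_ids, true_log2fc=log2fc, is_de=is_de, mu_a=mu_a, mu_b=mu_b)
        ),
        cells=pd.DataFrame(dict(cell_id=cell_ids, group=groups.to_numpy(), depth_factor=depth)),
    )
    return counts_df, groups, truth


def simulate_annotation(
    n_terms: int,
    term_size_range: tuple[int, int],
    enriched_terms: int,
    gene_universe: Sequence[str],
    de_genes: Sequence[str] = (),
    enriched_de_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-set annotation table with planted enriched terms.

    Enriched terms draw ``enriched_de_fraction`` of their members from
    ``de_genes`` and the rest uniformly from the universe; null terms draw
    uniformly from the universe. Returns (annotation with columns
    term_id/term_name/gene_id, truth with term_id/enriched).
    """
    lo, hi = term_size_range
    universe = list(dict.fromkeys(gene_universe))
    if lo < 1:
        raise ValueError("term sizes must be >= 1")
    if hi > len(universe):
        raise ValueError("term sizes cannot exceed the universe size")
    if enriched_terms > n_terms:
        raise ValueError("enriched_terms cannot exceed n_terms")
    de = [g for g in dict.fromkeys(de_genes)]
    missing = set(de) - set(universe)
    if missing:
        raise ValueError(f"DE genes absent from universe: {sorted(missing)[:5]}")
    need = math.ceil(enriched_de_fraction * hi)
    if enriched_terms > 0 and need > len(de):
        raise ValueError(
            f"enrichment infeasible: terms need up to {need} DE members but only {len(de)} DE genes given"
        )
    rng = np.random.default_rng(seed)
    uni = np.asarray(universe, dtype=object)
    de_arr = np.asarray(de, dtype=object)
    rows, truth_rows = [], []
    for k in range(n_terms):
        term_id = f"TERM:{k:04d}"
        size = int(rng.integers(lo, hi + 1))
        enriched = k < enriched_terms
        if enriched:
            n_from_de = min(int(round(enriched_de_fraction * size)), len(de_arr))
            members = list(rng.choice(de_arr, size=n_from_de, replace=False))
            rest = np.setdiff1d(uni, np.asarray(members, dtype=object), assume_unique=False)
            members += list(rng.choice(rest, size=size - n_from_de, replace=False))
        else:
            members = list(rng.choice(uni, size=size, replace=False))
        rows += [dict(term_id=term_id, term_name=f"synthetic term {k}", gene_id=g) for g in members]
        truth_rows.append(dict(term_id=term_id, enriched=enriched))
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
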