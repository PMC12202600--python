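"""Mechanistic model of nascent-RNA fluorescence at an active transcription site.

An active transcription site (TS) is detected in dual-color smFISH by signal
from intron-targeting probes, and its exon-probe fluorescence — expressed in
mature-RNA equivalents, i.e. normalized so a fully transcribed nascent RNA
contributes exactly 1.0 — reflects how far the engaged polymerases have
progressed along the gene. This module predicts the mean of that intensity
from the telegraph-model parameters by rejection sampling:

1. sample a promoter ON/OFF trajectory over an observation window,
2. place transcription-initiation events as an inhomogeneous Poisson process
   (rate mu while ON, 0 while OFF) and convert each event to a polymerase
   position assuming a constant elongation speed,
3. accept the sample only if at least one polymerase sits inside an intron
   downstream of an intron-probe target site (i.e. the TS would have been
   *detected*), otherwise reject and resample,
4. average the exon fluorescence of accepted samples.

Splicing is treated as instantaneous once an intron is fully transcribed, so
intron signal requires a polymerase still inside the intron and past a probe.
The measured intensity itself is modelled as Gamma-distributed with this mean
and a free variance parameter beta (moment matching).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .telegraph import TelegraphParams, active_fraction

__all__ = [
    "GeneModel",
    "PromoterTrajectory",
    "PolymeraseConfiguration",
    "NascentMeanEstimate",
    "InfeasibleParameterError",
    "sample_promoter_trajectory",
    "sample_polymerase_positions",
    "intron_signal_present",
    "exon_fluorescence",
    "mean_active_ts_intensity",
    "gamma_intensity_loglik",
    "sample_gamma_intensity",
]

SECONDS_PER_HOUR = 3600.0


class InfeasibleParameterError(RuntimeError):
    """Rejection-sampling acceptance rate fell below the feasibility floor."""


@dataclass(frozen=True)
class GeneModel:
    """Gene geometry and probe layout for nascent-fluorescence prediction.

    Positions are 0-based base-pair coordinates in ``[0, length_bp)``; intron
    intervals are half-open ``[start, end)``. Probe sets are unevenly tiled in
    real designs, which is exactly why position-resolved fluorescence matters.
    """

    length_bp: int
    exon_probe_positions: tuple[int, ...]
    intron_probe_positions: tuple[int, ...]
    intron_intervals: tuple[tuple[int, int], ...]
    elongation_bp_per_s: float = 50.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_probe_positions", tuple(sorted(self.exon_probe_positions)))
        object.__setattr__(self, "intron_probe_positions", tuple(sorted(self.intron_probe_positions)))
        object.__setattr__(
            self, "intron_intervals", tuple(sorted(tuple(iv) for iv in self.intron_intervals))
        )
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.elongation_bp_per_s <= 0:
            raise ValueError("elongation_bp_per_s must be positive")
        if not self.exon_probe_positions:
            raise ValueError("need at least one exon probe")
        if not self.intron_probe_positions:
            raise ValueError("need at least one intron probe")
        for x in self.exon_probe_positions + self.intron_probe_positions:
            if not (0 <= x < self.length_bp):
                raise ValueError(f"probe position {x} outside [0, {self.length_bp})")
        prev_end = -1
        for s, e in self.intron_intervals:
            if not (0 <= s < e <= self.length_bp):
                raise ValueError(f"bad intron interval [{s}, {e})")
            if s <= prev_end:
                raise ValueError("intron intervals must be disjoint and sorted")
            prev_end = e
        for x in self.intron_probe_positions:
            if sum(s <= x < e for s, e in self.intron_intervals) != 1:
                raise ValueError(f"intron probe {x} not inside exactly one intron interval")

    @property
    def window_s(self) -> float:
        """Observation window length: the gene traversal time length_bp / v."""
        return self.length_bp / self.elongation_bp_per_s

    def detection_boundaries(self) -> np.ndarray:
        """Flattened boundaries of the detectable-position union.

        A polymerase at position p produces intron signal iff p lies in some
        intron interval [s, e) at or past that interval's first probe x, i.e.
        in [x, e). Positions are detectable iff searchsorted(boundaries, p,
        'right') is odd.
        """
        bounds: list[float] = []
        for s, e in self.intron_intervals:
            probes = [x for x in self.intron_probe_positions if s <= x < e]
            if probes:
                bounds.extend((min(probes), e))
        return np.asarray(bounds, dtype=float)

    @classmethod
    def from_config(cls, cfg: dict) -> "GeneModel":
        """Build from a plain dict (the JSON/YAML gene-config schema)."""
        return cls(
            length_bp=int(cfg["gene_length_bp"]),
            exon_probe_positions=tuple(int(x) for x in cfg["exon_probes"]),
            intron_probe_positions=tuple(int(x) for x in cfg["intron_probes"]),
            intron_intervals=tuple((int(s), int(e)) for s, e in cfg["introns"]),
            elongation_bp_per_s=float(cfg.get("elongation_bp_per_s", 50.0)),
        )

    def to_config(self) -> dict:
        return {
            "gene_length_bp": self.length_bp,
            "elongation_bp_per_s": self.elongation_bp_per_s,
            "introns": [list(iv) for iv in self.intron_intervals],
            "exon_probes": list(self.exon_probe_positions),
            "intron_probes": list(self.intron_probe_positions),
        }


@dataclass(frozen=True)
class PromoterTrajectory:
    """Alternating ON/OFF segments exactly covering [window_start, window_end]."""

    window_start: float
    window_end: float
    segments: tuple[tuple[str, float, float], ...]  # (state, start, end)

    def __post_init__(self) -> None:
        t = self.window_start
        for state, s, e in self.segments:
            if state not in ("ON", "OFF"):
                raise ValueError(f"bad state {state!r}")
            if not (abs(s - t) < 1e-9 and e > s):
                raise ValueError("segments must be contiguous with positive duration")
            t = e
        if abs(t - self.window_end) > 1e-9:
            raise ValueError("segments must cover the window exactly")

    def on_time(self) -> float:
        return sum(e - s for state, s, e in self.segments if state == "ON")


@dataclass(frozen=True)
class PolymeraseConfiguration:
    """Multiset of polymerase positions (bp) on the gene at observation time."""

    positions_bp: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.positions_bp):
            raise ValueError("positions must be strictly positive")


@dataclass(frozen=True)
class NascentMeanEstimate:
    """Rejection-sampling estimate of the mean active-TS exon fluorescence."""

    mean_intensity: float
    n_accepted: int
    acceptance_rate: float


def sample_promoter_trajectory(
    params: TelegraphParams, window_s: float, rng: np.random.Generator
) -> PromoterTrajectory:
    """Stationary telegraph trajectory over [0, window_s].

    The initial state is drawn from the stationary law (ON with probability
    f = lam/(lam+gam)); holding times are exponential with rate gam leaving ON
    and lam leaving OFF (rates converted from 1/h to 1/s).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    lam_s = params.lam / SECONDS_PER_HOUR
    gam_s = params.gam / SECONDS_PER_HOUR
    state = "ON" if rng.random() < active_fraction(params) else "OFF"
    t = 0.0
    segments: list[tuple[str, float, float]] = []
    while t < window_s:
        rate = gam_s if state == "ON" else lam_s
        dt = rng.exponential(1.0 / rate)
        end = min(t + dt, window_s)
        segments.append((state, t, end))
        t = end
        state = "OFF" if state == "ON" else "ON"
    return PromoterTrajectory(0.0, window_s, tuple(segments))


def sample_polymerase_positions(
    traj: PromoterTrajectory, mu: float, gene: GeneModel, rng: np.random.Generator
) -> PolymeraseConfiguration:
    """Polymerase positions at the end of the trajectory window.

    Initiations form a Poisson process with rate mu (1/h) on ON segments and
    rate 0 on OFF segments; an initiation at time t sits at position
    v*(t_obs - t) at the observation time t_obs = window_end. Initiations
    mapping beyond the gene end have terminated and are dropped.
    """
    window = traj.window_end - traj.window_start
    if window < gene.window_s - 1e-9:
        raise ValueError(
            f"window {window:.1f}s shorter than gene traversal time {gene.window_s:.1f}s"
        )
    mu_s = mu / SECONDS_PER_HOUR
    v = gene.elongation_bp_per_s
    positions: list[float] = []
    for state, s, e in traj.segments:
        if state != "ON":
            continue
        n = rng.poisson(mu_s * (e - s))
        for t in s + (e - s) * rng.random(n):
            pos = v * (traj.window_end - t)
            if 0 < pos <= gene.length_bp:
                positions.append(pos)
    return PolymeraseConfiguration(tuple(positions))


def intron_signal_present(config: PolymeraseConfiguration, gene: GeneModel) -> bool:
    """Whether the configuration would light up at least one intron probe.

    True iff some polymerase resides inside an intron interval downstream of
    (at or past) an intron-probe target in that same interval — the probe's
    target has been transcribed but the intron is not yet complete (fast
    splicing removes completed introns instantly).
    """
    if not config.positions_bp:
        return False
    bounds = gene.detection_boundaries()
    if bounds.size == 0:
        return False
    pos = np.asarray(config.positions_bp)
    return bool(np.any(np.searchsorted(bounds, pos, side="right") % 2 == 1))


def exon_fluorescence(config: PolymeraseConfiguration, gene: GeneModel) -> float:
    """Total exon fluorescence in mature-RNA equivalents.

    Each nascent transcript contributes (number of exon probes already
    transcribed) / (total exon probes), so a complete transcript contributes
    exactly 1.0 — matching normalization by the average mature-spot intensity.
    """
    if not config.positions_bp:
        return 0.0
    probes = np.asarray(gene.exon_probe_positions, dtype=float)
    pos = np.asarray(config.positions_bp)
    return float(np.searchsorted(probes, pos, side="right").sum() / probes.size)


def _simulate_batch(
    params: TelegraphParams, gene: GeneModel, batch: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized batch of (exon fluorescence z, intron-signal accept flag).

    Equivalent to `sample_promoter_trajectory` + `sample_polymerase_positions`
    + detection/fluorescence per sample, but drawn as flat arrays so the
    rejection sampler stays cheap inside an MCMC loop.
    """
    T = gene.window_s
    v = gene.elongation_bp_per_s
    lam_s = params.lam / SECONDS_PER_HOUR
    gam_s = params.gam / SECONDS_PER_HOUR
    mu_s = params.mu / SECONDS_PER_HOUR
    f = active_fraction(params)

    init_on = rng.random(batch) < f
    # Alternating holding times; column j has state init_on XOR (j odd).
    cols: list[np.ndarray] = []
    total = np.zeros(batch)
    j = 0
    while True:
        on_col = init_on ^ (j % 2 == 1)
        rate = np.where(on_col, gam_s, lam_s)
        dur = rng.exponential(1.0, size=batch) / rate
        cols.append(dur)
        total += dur
        j += 1
        if total.min() >= T:
            break
        if j > 4096:
            raise RuntimeError("trajectory switch count exceeded bound; rates implausibly fast")
    E = np.stack(cols, axis=1)  # (batch, S) holding times
    S = E.shape[1]
    ends = np.minimum(np.cumsum(E, axis=1), T)
    starts = np.concatenate([np.zeros((batch, 1)), ends[:, :-1]], axis=1)
    on_mask = np.ones((batch, S), dtype=bool)
    on_mask[:, 1::2] = False
    on_mask ^= ~init_on[:, None]
    dur_on = np.where(on_mask, ends - starts, 0.0)
    on_time = dur_on.sum(axis=1)

    n_events = rng.poisson(mu_s * on_time)
    rows = np.repeat(np.arange(batch), n_events)
    u = rng.random(rows.size) * on_time[rows]
    cum = np.cumsum(dur_on, axis=1)
    # segment index: first ON column whose cumulative ON time exceeds u
    seg = (cum[rows] <= u[:, None]).sum(axis=1)
    prev = cum[rows, seg] - dur_on[rows, seg]
    t_event = starts[rows, seg] + (u - prev)
    pos = v * (T - t_event)  # in (0, L] since t_event in [0, T)

    probes = np.asarray(gene.exon_probe_positions, dtype=float)
    contrib = np.searchsorted(probes, pos, side="right") / probes.size
    z = np.bincount(rows, weights=contrib, minlength=batch)

    bounds = gene.detection_boundaries()
    if bounds.size:
        detected = np.searchsorted(bounds, pos, side="right") % 2 == 1
    else:
        detected = np.zeros(pos.size, dtype=bool)
    accept = np.bincount(rows[detected], minlength=batch) > 0
    return z, accept


def mean_active_ts_intensity(
    params: TelegraphParams,
    gene: GeneModel,
    n_samples: int = 1000,
    rng: np.random.Generator | None = None,
    max_proposals: int = 1_000_000,
    min_acceptance: float = 1e-4,
) -> NascentMeanEstimate:
    """Mean exon fluorescence at a *detected* (active) TS, by rejection sampling.

    Repeats trajectory -> polymerase placement, accepting a sample only when
    the intron signal would be present, until ``n_samples`` are accepted. The
    estimate depends on lam, gam and mu only (not delta or beta) and is
    deterministic given the generator state.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    zs: list[np.ndarray] = []
    n_acc = 0
    n_prop = 0
    batch = max(1024, 2 * n_samples)
    while n_acc < n_samples:
        z, accept = _simulate_batch(params, gene, batch, rng)
        zs.append(z[accept])
        n_acc += int(accept.sum())
        n_prop += batch
        if n_prop >= max_proposals and n_acc / n_prop < min_acceptance:
            raise InfeasibleParameterError(
                f"acceptance rate {n_acc / n_prop:.2e} below {min_acceptance:.0e} "
                f"after {n_prop} proposals (mu or f too small?)"
            )
    z_acc = np.concatenate(zs)[:n_samples]
    return NascentMeanEstimate(
        mean_intensity=float(z_acc.mean()),
        n_accepted=n_samples,
        acceptance_rate=n_acc / n_prop,
    )


def gamma_intensity_loglik(z, nu: float, beta: float):
    """Log-density of the moment-matched Gamma intensity law.

    Shape nu^2/beta and scale beta/nu give mean nu and variance beta. Accepts
    a scalar or array of intensities z > 0 (TS intensities are positive by
    construction; non-positive values are rejected).
    """
    if nu <= 0 or beta <= 0:
        raise ValueError("nu and beta must be positive")
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr <= 0):
        raise ValueError("intensities must be strictly positive")
    shape = nu * nu / beta
    scale = beta / nu
    out = (shape - 1.0) * np.log(z_arr) - z_arr / scale - special.gammaln(shape) - shape * np.log(scale)
    return float(out) if np.isscalar(z) or z_arr.ndim == 0 else out


def sample_gamma_intensity(
    nu: float, beta: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws from the moment-matched Gamma intensity law (mean nu, variance beta)."""
    if nu <= 0 or beta <= 0:
        raise ValueError("nu and beta must be positive")
    return rng.gamma(shape=nu * nu / beta, scale=beta / nu, size=size)
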