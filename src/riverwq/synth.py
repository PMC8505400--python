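"""Synthetic sampling-campaign generator.

Emulates the study design the package targets: 11 industrial-discharge
sites on a river stretch sampled in three phases (pre-lockdown, lockdown,
unlock), 20 physico-chemical/biological parameters per sample.  Each
parameter is drawn independently from a normal distribution with the
configured per-phase mean and SD, truncated below at 0 (pH truncated to
[0, 14], Secchi depth strictly positive), so no generated record violates
the sample invariants.

Only marginal moments are emulated; cross-parameter correlations are not
imposed by default.  An optional Gaussian-copula hook accepts a user
correlation matrix for higher-fidelity draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .registry import PHASES, SampleRecord

__all__ = ["PHASE_STATISTICS", "SyntheticSpec", "generate", "phase_means"]

#: Per-parameter (mean, SD) for each study phase — the descriptive
#: statistics of the monitored campaign that the generator reproduces.
#: Units: ions/BOD/DO mg/l; metals/TP/Chl-a µg/l; EC µS/cm; turbidity NTU;
#: Secchi depth m.
PHASE_STATISTICS: dict[str, dict[str, tuple[float, float]]] = {
    "ph":        {"pre_lockdown": (7.46, 0.38),      "lockdown": (6.92, 0.48),    "unlock": (7.42, 0.49)},
    "tds":       {"pre_lockdown": (740.65, 50.24),   "lockdown": (524.85, 26.29), "unlock": (589.96, 48.30)},
    "turbidity": {"pre_lockdown": (20.73, 4.42),     "lockdown": (5.63, 3.52),    "unlock": (11.36, 5.66)},
    "ec":        {"pre_lockdown": (1157.27, 78.50),  "lockdown": (820.09, 41.09), "unlock": (921.82, 75.47)},
    "mg":        {"pre_lockdown": (70.36, 11.00),    "lockdown": (27.00, 3.00),   "unlock": (46.81, 4.97)},
    "ca":        {"pre_lockdown": (131.09, 34.13),   "lockdown": (64.81, 9.48),   "unlock": (99.54, 23.89)},
    "cl":        {"pre_lockdown": (407.27, 65.13),   "lockdown": (198.18, 17.21), "unlock": (264.54, 27.69)},
    "so4":       {"pre_lockdown": (358.18, 41.19),   "lockdown": (127.27, 34.37), "unlock": (199.09, 68.62)},
    "no3":       {"pre_lockdown": (86.45, 9.60),     "lockdown": (37.46, 5.48),   "unlock": (64.23, 15.77)},
    "bod":       {"pre_lockdown": (12.54, 3.47),     "lockdown": (7.27, 2.41),    "unlock": (9.81, 2.71)},
    "do":        {"pre_lockdown": (4.87, 0.49),      "lockdown": (7.29, 0.60),    "unlock": (6.344, 5.01)},
    "zn":        {"pre_lockdown": (39845.45, 6280.34), "lockdown": (5300.00, 762.88), "unlock": (7566.36, 739.20)},
    "cd":        {"pre_lockdown": (10.20, 1.77),     "lockdown": (3.10, 1.33),    "unlock": (5.01, 1.28)},
    "pb":        {"pre_lockdown": (26.18, 5.23),     "lockdown": (3.53, 1.66),    "unlock": (5.36, 1.56)},
    "ni":        {"pre_lockdown": (84.55, 33.57),    "lockdown": (6.54, 1.63),    "unlock": (22.36, 4.20)},
    "cr":        {"pre_lockdown": (87.67, 10.32),    "lockdown": (33.85, 6.33),   "unlock": (41.15, 7.98)},
    "fe":        {"pre_lockdown": (674.82, 112.96),  "lockdown": (132.90, 8.67),  "unlock": (284.36, 83.46)},
    "sd":        {"pre_lockdown": (2.24, 0.45),      "lockdown": (2.79, 0.46),    "unlock": (2.55, 0.43)},
    "chla":      {"pre_lockdown": (76.09, 16.85),    "lockdown": (29.18, 9.00),   "unlock": (49.36, 8.86)},
    "tp":        {"pre_lockdown": (62.45, 17.32),    "lockdown": (18.36, 6.10),   "unlock": (33.00, 7.12)},
}

_BOUNDS = {"ph": (0.0, 14.0)}  # everything else: [0, inf)


def phase_means(phase: str) -> dict[str, float]:
    """The configured location vector of one phase (code → mean)."""
    return {code: stats_[phase][0] for code, stats_ in PHASE_STATISTICS.items()}


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of one synthetic campaign.

    ``statistics`` maps code → phase → (location, scale); defaults are the
    package's study-condition table above.  ``correlation`` optionally
    supplies a Gaussian-copula correlation matrix over ``sorted(codes)``.
    """

    n_sites: int = 11
    phases: tuple[str, ...] = PHASES
    statistics: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: PHASE_STATISTICS
    )
    seed: int = 0
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError(f"n_sites must be positive, got {self.n_sites}")
        for code, per_phase in self.statistics.items():
            lo, hi = _BOUNDS.get(code, (0.0, np.inf))
            for phase in self.phases:
                loc, scale = per_phase[phase]
                if scale < 0:
                    raise ValueError(f"{code}/{phase}: scale {scale} < 0")
                if not lo <= loc <= hi:
                    raise ValueError(
                        f"{code}/{phase}: location {loc} outside truncation bounds"
                    )


def _calibrated_loc(target: float, scale: float, lo: float, hi: float) -> float:
    """Underlying normal location whose truncated mean equals ``target``.

    Truncating at the bounds shifts the realized mean away from the raw
    location (upward for a lower bound near the bulk of the mass); for
    high-CV parameters the shift would bias every downstream linear index.
    Solving for the location keeps the configured mean exact in
    expectation.  The truncated mean is strictly increasing in the
    location, so a bracketing root find is safe.
    """
    def shifted_mean(mu: float) -> float:
        a, b = (lo - mu) / scale, (hi - mu) / scale
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=scale))

    if abs(shifted_mean(target) - target) < 1e-12 * max(1.0, abs(target)):
        return target
    return brentq(
        lambda mu: shifted_mean(mu) - target,
        target - 20 * scale,
        target + 20 * scale,
        xtol=1e-12 * max(1.0, abs(target)),
    )


def _truncnorm_draw(
    rng: np.random.Generator, loc: float, scale: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if scale == 0:
        return np.full(size, loc)
    mu = _calibrated_loc(loc, scale, lo, hi)
    a, b = (lo - mu) / scale, (hi - mu) / scale
    return stats.truncnorm.rvs(a, b, loc=mu, scale=scale, size=size, random_state=rng)


def _copula_draw(
    rng: np.random.Generator,
    codes: Sequence[str],
    spec: SyntheticSpec,
    phase: str,
) -> np.ndarray:
    corr = np.asarray(spec.correlation, dtype=float)
    if corr.shape != (len(codes), len(codes)):
        raise ValueError(
            f"correlation matrix shape {corr.shape} does not match {len(codes)} codes"
        )
    z = rng.multivariate_normal(np.zeros(len(codes)), corr, size=spec.n_sites)
    u = stats.norm.cdf(z)
    out = np.empty_like(u)
    for j, code in enumerate(codes):
        loc, scale = spec.statistics[code][phase]
        lo, hi = _BOUNDS.get(code, (0.0, np.inf))
        if scale == 0:
            out[:, j] = loc
            continue
        mu = _calibrated_loc(loc, scale, lo, hi)
        a, b = (lo - mu) / scale, (hi - mu) / scale
        out[:, j] = stats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=scale)
    return out


def generate(spec: SyntheticSpec) -> list[SampleRecord]:
    """Draw ``n_sites`` records per phase; deterministic under ``spec.seed``.

    Sites are labelled S1…Sn.  With ``scale = 0`` everywhere each record
    equals the location vector exactly.
    """
    rng = np.random.default_rng(spec.seed)
    codes = sorted(spec.statistics)
    records: list[SampleRecord] = []
    for phase in spec.phases:
        if spec.correlation is not None:
            matrix = _copula_draw(rng, codes, spec, phase)
        else:
            matrix = np.column_stack(
                [
                    _truncnorm_draw(
                        rng,
                        *spec.statistics[code][phase],
                        *_BOUNDS.get(code, (0.0, np.inf)),
                        spec.n_sites,
                    )
                    for code in codes
                ]
            )
        for i in range(spec.n_sites):
            records.append(
                SampleRecord(
                    site_id=f"S{i + 1}",
                    phase=phase,
                    values={c: float(matrix[i, j]) for j, c in enumerate(codes)},
                )
            )
    return records
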