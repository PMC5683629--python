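"""Incidence-based species richness: rarefaction, Chao2, CI overlap.

Sample-based rarefaction gives the expected number of species found in h of
the m sampling events, averaging over all C(m, h) equally likely subsets:

    tau(h) = sum_j [ 1 - C(m - Y_j, h) / C(m, h) ]

where Y_j is the number of events containing species j. The variance
reported with each point is the unconditional (estimator-based) form

    var(h) = sum_j (1 - alpha_jh)^2 - tau(h)^2 / S_est,   alpha_jh = C(m-Y_j,h)/C(m,h)

with S_est the Chao2 estimate of total richness; it is non-negative whenever
S_est >= S_obs (Cauchy-Schwarz) and, unlike the conditional subset variance,
stays positive at h = m while undetected species remain, so full-effort
curves still carry uncertainty.

Chao2 estimates total richness from the species found in exactly one (Q1)
and exactly two (Q2) events; its confidence interval uses the standard
log-normal construction on the excess T = estimate - S_obs. Intervals default
to the 84% two-sided level (z = 1.4051): non-overlap of two 84% intervals
corresponds approximately to a test at P = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpecimenRecord

__all__ = ["IncidenceMatrix", "RarefactionCurve", "RichnessEstimate",
           "build_incidence", "rarefaction", "chao2", "ci_overlap",
           "Z_84"]

#: two-sided normal quantile for an 84% confidence interval
Z_84 = 1.4051


@dataclass
class IncidenceMatrix:
    """Binary species x sampling-event presence matrix with incidence counts."""

    table: pd.DataFrame  # bool, rows=species, columns=events

    def __post_init__(self):
        self.table = self.table.astype(bool)
        y = self.table.sum(axis=1)
        if (y == 0).any():
            self.table = self.table.loc[y > 0]

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    @property
    def events(self) -> list[str]:
        return list(self.table.columns)

    @property
    def m(self) -> int:
        return self.table.shape[1]

    @property
    def s_obs(self) -> int:
        return self.table.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Number of events containing each species."""
        return self.table.sum(axis=1).to_numpy()

    @property
    def q1(self) -> int:
        return int((self.y == 1).sum())

    @property
    def q2(self) -> int:
        return int((self.y == 2).sum())


@dataclass
class RarefactionPoint:
    h: int
    tau: float
    var: float
    lo84: float
    hi84: float


@dataclass
class RarefactionCurve:
    points: list[RarefactionPoint]
    z: float = Z_84

    @property
    def m(self) -> int:
        return self.points[-1].h

    def at(self, h: int) -> RarefactionPoint:
        for p in self.points:
            if p.h == h:
                return p
        raise KeyError(f"no rarefaction point at h={h}")


@dataclass
class RichnessEstimate:
    estimator: str
    point: float
    var: float
    lo84: float
    hi84: float
    z: float = Z_84
    s_obs: int = 0


def build_incidence(records: list[SpecimenRecord], species_of,
                    scope=None) -> IncidenceMatrix:
    """Tally presence of each species in each sampling event.

    ``species_of`` maps a record to its species label — pass e.g.
    ``lambda r: assignment.name_of(r.specimen_id)`` for barcode OTUs or
    ``lambda r: r.field_label`` for field identifications; records mapping to
    ``None`` are skipped. ``scope`` is a site name or predicate as in
    :func:`barcodeaudit.concordance.audit`.
    """
    cells: dict[tuple[str, str], bool] = {}
    events: list[str] = []
    species: list[str] = []
    for r in records:
        if r.role != "survey":
            continue
        if scope is not None and not (scope(r) if callable(scope) else r.site == scope):
            continue
        sp = species_of(r)
        if sp is None or not r.sampling_event:
            continue
        if r.sampling_event not in events:
            events.append(r.sampling_event)
        if sp not in species:
            species.append(sp)
        cells[(sp, r.sampling_event)] = True
    if not events:
        raise ValueError("no sampling events in scope")
    table = pd.DataFrame(False, index=species, columns=events)
    for (sp, ev) in cells:
        table.loc[sp, ev] = True
    return IncidenceMatrix(table)


def _alpha(m: int, y: np.ndarray, h: int) -> np.ndarray:
    """P(species absent from a random h-subset of events) = C(m-y, h)/C(m, h)."""
    denom = math.comb(m, h)
    return np.array([math.comb(m - yi, h) / denom if m - yi >= h else 0.0
                     for yi in y])


def rarefaction(inc: IncidenceMatrix, z: float = Z_84,
                s_est: float | None = None) -> RarefactionCurve:
    """Analytic sample-based rarefaction curve with 84% confidence bands.

    ``s_est`` overrides the total-richness estimate used by the unconditional
    variance; by default the Chao2 point estimate of ``inc`` is used.
    """
    m, y = inc.m, inc.y
    if m < 1:
        raise ValueError("need at least one sampling event")
    if s_est is None:
        s_est = chao2_point(inc)
    points = []
    for h in range(1, m + 1):
        a = _alpha(m, y, h)
        tau = float((1 - a).sum())
        var = float(((1 - a) ** 2).sum() - tau ** 2 / s_est)
        var = max(var, 0.0)
        half = z * math.sqrt(var)
        points.append(RarefactionPoint(h=h, tau=tau, var=var,
                                       lo84=max(tau - half, 0.0),
                                       hi84=tau + half))
    return RarefactionCurve(points=points, z=z)


def chao2_point(inc: IncidenceMatrix) -> float:
    """Chao2 point estimate (classic form, bias-corrected when Q2 = 0)."""
    m, s_obs, q1, q2 = inc.m, inc.s_obs, inc.q1, inc.q2
    if m < 2:
        raise ValueError("Chao2 needs at least two sampling events")
    k = (m - 1) / m
    if q2 > 0:
        return s_obs + k * q1 * q1 / (2 * q2)
    return s_obs + k * q1 * (q1 - 1) / 2


def chao2(inc: IncidenceMatrix, z: float = Z_84) -> RichnessEstimate:
    """Chao2 richness estimate with log-normal 84% confidence interval.

    The CI is built on T = estimate - S_obs:
    R = exp(z * sqrt(ln(1 + var / T^2))), CI = [S_obs + T/R, S_obs + T*R];
    with Q1 = 0 the estimate equals S_obs and the interval is degenerate.
    """
    m, s_obs, q1, q2 = inc.m, inc.s_obs, inc.q1, inc.q2
    est = chao2_point(inc)
    k = (m - 1) / m
    if q1 == 0:
        return RichnessEstimate("chao2", float(s_obs), 0.0, float(s_obs),
                                float(s_obs), z=z, s_obs=s_obs)
    if q2 > 0:
        r = q1 / q2
        var = q2 * (0.5 * k * r ** 2 + k ** 2 * r ** 3 + 0.25 * k ** 2 * r ** 4)
    else:
        var = (k * q1 * (q1 - 1) / 2 + k ** 2 * q1 * (2 * q1 - 1) ** 2 / 4
               - k ** 2 * q1 ** 4 / (4 * est))
    var = max(var, 0.0)
    t = est - s_obs
    if t <= 0 or var == 0:
        return RichnessEstimate("chao2", est, var, float(s_obs), est, z=z,
                                s_obs=s_obs)
    r_fac = math.exp(z * math.sqrt(math.log(1 + var / t ** 2)))
    return RichnessEstimate("chao2", est, var,
                            lo84=s_obs + t / r_fac, hi84=s_obs + t * r_fac,
                            z=z, s_obs=s_obs)


def bootstrap_chao2(inc: IncidenceMatrix, n_boot: int = 500,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Chao2 point estimates over event-resampled (with replacement) replicates.

    The empirical variance of the returned vector is the resampling oracle
    against which the analytic Chao2 variance is checked.
    """
    rng = rng or np.random.default_rng()
    mat = inc.table.to_numpy()
    m = inc.m
    out = np.empty(n_boot)
    for b in range(n_boot):
        cols = rng.integers(0, m, size=m)
        boot = mat[:, cols]
        y = boot.sum(axis=1)
        y = y[y > 0]
        s_obs = len(y)
        q1 = int((y == 1).sum())
        q2 = int((y == 2).sum())
        k = (m - 1) / m
        if q2 > 0:
            out[b] = s_obs + k * q1 * q1 / (2 * q2)
        else:
            out[b] = s_obs + k * q1 * (q1 - 1) / 2
    return out


def ci_overlap(a, b, h: int | None = None) -> str:
    """Compare two 84% intervals; disjoint -> ``"significant"``.

    ``a``/``b`` are :class:`RarefactionCurve` (compared at ``h``, defaulting
    to the smaller of the two efforts) or :class:`RichnessEstimate`.
    """
    za = getattr(a, "z", None)
    zb = getattr(b, "z", None)
    if za is not None and zb is not None and not math.isclose(za, zb):
        raise ValueError("mismatched confidence levels")

    def interval(x):
        if isinstance(x, RarefactionCurve):
            point = x.at(h if h is not None else min_m)
            return point.lo84, point.hi84
        return x.lo84, x.hi84

    if isinstance(a, RarefactionCurve) and isinstance(b, RarefactionCurve):
        min_m = min(a.m, b.m)
        if h is not None and h > min_m:
            raise ValueError(f"h={h} exceeds the shorter curve (m={min_m})")
    else:
        min_m = None
    lo_a, hi_a = interval(a)
    lo_b, hi_b = interval(b)
    disjoint = hi_a < lo_b or hi_b < lo_a
    return "significant" if disjoint else "not_significant"
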