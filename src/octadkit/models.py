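"""Model/Results front-end over the analytical core.

Each model is constructed from data (an octad table, a tetrad tally, a
segregant fraction, a growth curve), ``fit()`` returns a results object
carrying estimates, their uncertainties and diagnostics, and every results
object renders a ``summary()`` table.  The heavy lifting lives in
:mod:`octadkit.analysis`, :mod:`octadkit.sim` and :mod:`octadkit.growth`;
this layer only shapes the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import analysis, growth, sim
from .io import CrossDef, MarkerDef, OctadTable

__all__ = [
    "TetradLinkage",
    "TetradLinkageResults",
    "NuclearOrientation",
    "NuclearOrientationResults",
    "IodineLoci",
    "IodineLociResults",
    "GrowthModel",
    "GrowthResults",
]


def _rule(width: int = 58) -> str:
    return "-" * width


# ---------------------------------------------------------------------------
# tetrad linkage


class TetradLinkage:
    """Two-point linkage model for a marker pair from tetrad counts.

    Build from explicit PD/NPD/TT counts or from an octad table via
    :meth:`from_table`.  ``fit()`` estimates the Perkins map distance and
    tests linkage by the PD-vs-NPD chi-square (1 df).
    """

    def __init__(self, counts: analysis.TetradCounts):
        self.counts = counts

    @classmethod
    def from_counts(
        cls, pd: int, npd: int, tt: int, marker_a: str = "a", marker_b: str = "b"
    ) -> "TetradLinkage":
        return cls(
            analysis.TetradCounts(pd=pd, npd=npd, tt=tt, marker_a=marker_a, marker_b=marker_b)
        )

    @classmethod
    def from_table(
        cls,
        table: OctadTable,
        marker_a: Union[str, MarkerDef],
        marker_b: Union[str, MarkerDef],
    ) -> "TetradLinkage":
        return cls(analysis.tally_tetrads(table, marker_a, marker_b))

    def fit(self, alpha: float = 0.05) -> "TetradLinkageResults":
        distance = analysis.perkins_distance(self.counts)
        test = analysis.linkage_test(self.counts, alpha=alpha)
        # delta-method standard error of the Perkins estimate from the
        # multinomial (PD, NPD, TT) sample
        n = self.counts.total
        p_tt = self.counts.tt / n
        p_npd = self.counts.npd / n
        per_tetrad = 100.0 * (
            np.array([0.0, 3.0, 0.5]) - (p_tt / 2.0 + 3.0 * p_npd)
        )  # centred contributions of PD, NPD, TT
        var = (
            per_tetrad[0] ** 2 * (1 - p_tt - p_npd)
            + per_tetrad[1] ** 2 * p_npd
            + per_tetrad[2] ** 2 * p_tt
        )
        se = math.sqrt(var / n)
        return TetradLinkageResults(
            counts=self.counts,
            map_distance_cM=distance,
            map_distance_se=se,
            chi2=test.chi2,
            pvalue=test.pvalue,
            linked=test.linked,
            alpha=alpha,
        )


@dataclass(frozen=True)
class TetradLinkageResults:
    counts: analysis.TetradCounts
    map_distance_cM: float
    map_distance_se: float
    chi2: float
    pvalue: float
    linked: bool
    alpha: float

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Tetrad linkage: " f"{c.marker_a} - {c.marker_b}",
            _rule(),
            f"PD : NPD : TT            {c.pd} : {c.npd} : {c.tt}   (n = {c.total})",
            f"Perkins map distance     {self.map_distance_cM:.1f} cM"
            f"  (SE {self.map_distance_se:.1f})",
            f"PD vs NPD chi-square     {self.chi2:.2f}  (1 df)",
            f"p-value                  {self.pvalue:.3g}",
            f"linked (alpha={self.alpha:g})      {self.linked}",
            _rule(),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# nuclear orientation


class NuclearOrientation:
    """Nuclear-arrangement inference from linear-ascus octads.

    Measures adjacent-pair discordance on the table and compares it with
    the nulls implied by candidate arrangement models (exact zero for
    ``linear_ordered``; Monte-Carlo otherwise).
    """

    def __init__(self, table: OctadTable):
        self.table = table

    def fit(
        self,
        models: Sequence[str] = ("linear_ordered", "random_spores"),
        n_sims: int = 10000,
        seed: int = 0,
        viability: float = 1.0,
        alpha: float = 0.05,
    ) -> "NuclearOrientationResults":
        observed = analysis.adjacent_discordance(self.table)
        config = sim.SimConfig(
            cross=self.table.cross,
            n_asci=len(observed.per_ascus),
            viability=viability,
            seed=seed,
        )
        verdicts = tuple(
            analysis.orientation_test(
                observed, model, config=config, n_sims=n_sims, seed=seed, alpha=alpha
            )
            for model in models
        )
        return NuclearOrientationResults(observed=observed, verdicts=verdicts)


@dataclass(frozen=True)
class NuclearOrientationResults:
    observed: analysis.DiscordanceResult
    verdicts: tuple[analysis.OrientationVerdict, ...]

    def summary(self) -> str:
        o = self.observed
        lines = [
            "Nuclear orientation from adjacent-pair discordance",
            _rule(),
            f"discordant pairs         {o.discordant_pairs} / {o.total_pairs}"
            f"  (fraction {o.fraction:.3f})",
            f"asci included            {len(o.per_ascus)}"
            + (f"  (excluded: {len(o.excluded_asci)})" if o.excluded_asci else ""),
        ]
        for v in self.verdicts:
            lines.append(
                f"model {v.model_name:<18} null mean {v.null_mean:.3f}  "
                f"p {v.null_p:.3g}  reject={v.reject}"
            )
        lines.append(_rule())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# iodine multilocus model


class IodineLoci:
    """Unlinked-locus model for the iodine-staining trait.

    An iodine-positive segregant must carry the staining parent's allele
    at all n unlinked loci, so a fraction f of iod+ segregants implies
    n ≈ −log2(f).
    """

    def __init__(self, iod_positive_fraction: float):
        self.fraction = iod_positive_fraction

    def fit(self) -> "IodineLociResults":
        est = analysis.iod_locus_estimate(self.fraction)
        return IodineLociResults(estimate=est)


@dataclass(frozen=True)
class IodineLociResults:
    estimate: analysis.IodLociEstimate

    def summary(self) -> str:
        e = self.estimate
        return "\n".join(
            [
                "Iodine-trait unlinked-locus estimate",
                _rule(),
                f"iod+ segregant fraction  {e.fraction:.3f}",
                f"locus count (continuous) {e.n_hat:.2f}",
                f"locus count (nearest)    {e.n_nearest}",
                f"expected fraction at {e.n_nearest}  {100 * e.expected_fraction:.1f}%",
                _rule(),
            ]
        )


# ---------------------------------------------------------------------------
# growth


class GrowthModel:
    """Exponential-phase growth model for a density time series."""

    def __init__(self, curve: growth.GrowthCurve):
        self.curve = curve

    def fit(
        self,
        window: Optional[tuple[int, int]] = None,
        min_points: int = 4,
        r2_threshold: float = 0.98,
    ) -> "GrowthResults":
        fit = growth.fit_doubling_time(
            self.curve, window=window, min_points=min_points, r2_threshold=r2_threshold
        )
        return GrowthResults(curve=self.curve, fit=fit)


@dataclass(frozen=True)
class GrowthResults:
    curve: growth.GrowthCurve
    fit: growth.GrowthFit

    @property
    def doubling_time(self) -> float:
        return self.fit.doubling_time

    def summary(self) -> str:
        f = self.fit
        t = self.curve.times
        return "\n".join(
            [
                f"Growth fit{': ' + f.label if f.label else ''}",
                _rule(),
                f"doubling time            {f.doubling_time:.1f} min",
                f"log2 slope               {f.slope:.5f} /min",
                f"fitted window            points {f.window[0]}..{f.window[1] - 1}"
                f"  (t = {t[f.window[0]]:g}..{t[f.window[1] - 1]:g} min,"
                f" {f.n_points} points)",
                f"r-squared                {f.r_squared:.4f}",
                _rule(),
            ]
        )
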