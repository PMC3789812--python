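"""Octad analytics: sister matching, tetrad reduction and classification,
linkage statistics, adjacent-pair discordance, and the iodine multilocus
estimator.

The analytical chain mirrors how an octad cross is scored at the bench:

1. :func:`match_sisters` pairs the eight spores into the four mitotic
   sister pairs and deduces dead-spore genotypes (a dead spore must carry
   the live genotype that lacks a matching sister).
2. :func:`reduce_to_tetrad` collapses the octad to the four meiotic
   products.
3. :func:`classify_tetrad` / :func:`tally_tetrads` assign the classical
   PD / NPD / TT classes for a marker pair, from which
   :func:`perkins_distance` and :func:`linkage_test` derive map distance
   and a linkage verdict.
4. :func:`adjacent_discordance` and :func:`orientation_test` read nuclear
   arrangement off linear asci: if meiotic nuclei kept a strict linear
   order with mitotic daughters adjacent, every adjoining spore pair
   (A,B), (C,D), (E,F), (G,H) would be genotypically identical.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .io import (
    POSITIONS,
    UNKNOWN,
    CrossDef,
    Genotype,
    MarkerDef,
    MendelianError,
    Octad,
    OctadTable,
    SisterMatchError,
    SporeRecord,
    StructureError,
)

__all__ = [
    "ADJACENT_PAIRS",
    "SisterPairing",
    "Tetrad",
    "TetradCounts",
    "LinkageTest",
    "DiscordanceResult",
    "OrientationVerdict",
    "IodLociEstimate",
    "match_sisters",
    "impute_octad",
    "reduce_to_tetrad",
    "classify_tetrad",
    "tally_tetrads",
    "perkins_distance",
    "linkage_test",
    "adjacent_discordance",
    "orientation_test",
    "iod_locus_estimate",
]

#: Adjoining spore pairs of a linear ascus, the unit of the discordance
#: statistic.
ADJACENT_PAIRS = (("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"))


# ---------------------------------------------------------------------------
# sister matching and imputation


@dataclass(frozen=True)
class SisterPairing:
    """Decomposition of an octad into four identical sister pairs.

    ``pairs`` partition the positions A–H; ``genotypes`` maps every
    position to its (possibly imputed) genotype; ``imputed`` lists the
    dead-spore assignments that were made.  ``ambiguous`` is set when the
    assignment of genotypes to dead positions is not unique (two or more
    dead spores receiving two or more distinct genotypes, or a dead sister
    pair whose genotype cannot be deduced at all) — such asci are excluded
    from position-sensitive statistics.
    """

    ascus_id: str
    pairs: tuple[tuple[str, str], ...]
    genotypes: dict[str, Genotype]
    imputed: tuple[tuple[str, Genotype], ...]
    ambiguous: bool = False


def match_sisters(octad: Octad) -> SisterPairing:
    """Pair the spores of *octad* into four identical sister pairs,
    deducing dead-spore genotypes.

    Every live genotype class must occur an even number of times once dead
    spores are assigned; a class with odd multiplicity therefore donates
    its genotype to a dead spore.  Raises :class:`SisterMatchError` when no
    completion exists (odd class with no dead spore left) or when two or
    more whole sister pairs died (their genotypes are unrecoverable).
    """
    live = [(s.position, s.genotype) for s in octad.spores if s.viable]
    dead = [s.position for s in octad.spores if not s.viable]

    counts: Counter[Genotype] = Counter(g for _, g in live)
    odd = sorted(g for g, c in counts.items() if c % 2 == 1)
    if len(odd) > len(dead):
        raise SisterMatchError(
            f"ascus {octad.ascus_id}: genotype classes with odd counts "
            f"({len(odd)}) exceed dead spores ({len(dead)}); no sister "
            f"pairing exists"
        )
    spare = len(dead) - len(odd)  # always even (parity over 8 spores)
    if spare >= 4:
        raise SisterMatchError(
            f"ascus {octad.ascus_id}: {spare} dead spores beyond the odd "
            f"live classes would form >=2 dead sister pairs; genotypes are "
            f"unresolvable"
        )

    ambiguous = len(dead) >= 2 and len(set(odd)) >= 2
    imputed: list[tuple[str, Genotype]] = []
    genotypes: dict[str, Genotype] = {pos: g for pos, g in live}
    # deterministic assignment: dead positions in A–H order, odd genotypes
    # in sorted order; a remaining dead pair stays unknown
    for pos, g in zip(dead, odd):
        genotypes[pos] = g
        imputed.append((pos, g))
    if spare == 2:
        unknown = tuple(UNKNOWN for _ in octad.spores[0].genotype)
        for pos in dead[len(odd):]:
            genotypes[pos] = unknown
        ambiguous = True

    groups: dict[Genotype, list[str]] = {}
    for pos in POSITIONS:
        groups.setdefault(genotypes[pos], []).append(pos)
    pairs: list[tuple[str, str]] = []
    for g in sorted(groups):
        members = groups[g]
        if len(members) % 2 == 1:  # defensive; cannot happen after the above
            raise SisterMatchError(
                f"ascus {octad.ascus_id}: genotype class {g} has odd "
                f"multiplicity after imputation"
            )
        pairs.extend((members[i], members[i + 1]) for i in range(0, len(members), 2))
    pairs.sort()
    return SisterPairing(
        ascus_id=octad.ascus_id,
        pairs=tuple(pairs),
        genotypes=genotypes,
        imputed=tuple(imputed),
        ambiguous=ambiguous,
    )


def impute_octad(octad: Octad) -> Octad:
    """Return *octad* with dead-spore genotypes replaced by their
    sister-matching deductions (``imputed`` flags set)."""
    pairing = match_sisters(octad)
    spores = []
    for s in octad.spores:
        if s.viable:
            spores.append(s)
        else:
            spores.append(replace(s, genotype=pairing.genotypes[s.position], imputed=True))
    return replace(octad, spores=tuple(spores))


# ---------------------------------------------------------------------------
# tetrad reduction and classification


@dataclass(frozen=True)
class Tetrad:
    """The four meiotic products of one meiosis, as an unordered multiset
    (stored sorted)."""

    ascus_id: str
    products: tuple[Genotype, Genotype, Genotype, Genotype]

    def __post_init__(self) -> None:
        object.__setattr__(self, "products", tuple(sorted(self.products)))


def reduce_to_tetrad(octad: Octad) -> Tetrad:
    """Collapse an octad to its four meiotic products via sister matching.

    Checks 2:2 segregation of every marker among the products
    (:class:`MendelianError` otherwise, naming the offending marker index).
    """
    pairing = match_sisters(octad)
    products = tuple(pairing.genotypes[a] for a, _ in pairing.pairs)
    if any(UNKNOWN in g for g in products):
        raise SisterMatchError(
            f"ascus {octad.ascus_id}: unresolved dead sister pair; products "
            f"are incomplete"
        )
    n_markers = len(products[0])
    for idx in range(n_markers):
        alleles = Counter(g[idx] for g in products)
        if sorted(alleles.values()) != [2, 2]:
            raise MendelianError(
                f"ascus {octad.ascus_id}: marker #{idx} does not segregate "
                f"2:2 among products (counts {dict(alleles)})"
            )
    return Tetrad(ascus_id=octad.ascus_id, products=products)  # type: ignore[arg-type]


TetradClass = str  # "PD" | "NPD" | "TT"


def classify_tetrad(
    tetrad: Tetrad,
    marker_a: Union[str, MarkerDef],
    marker_b: Union[str, MarkerDef],
    cross: CrossDef,
) -> TetradClass:
    """Classify *tetrad* for a marker pair as PD, NPD or TT.

    PD: only the two parental two-locus combinations occur; NPD: only the
    two recombinant combinations; TT: two parental-class and two
    recombinant-class products (four distinct combinations).
    """
    ia, ib = cross.index(marker_a), cross.index(marker_b)
    combos = [(g[ia], g[ib]) for g in tetrad.products]
    for idx, name in ((ia, marker_a), (ib, marker_b)):
        counts = Counter(g[idx] for g in tetrad.products)
        if sorted(counts.values()) != [2, 2]:
            raise MendelianError(
                f"ascus {tetrad.ascus_id}: marker {name} does not segregate "
                f"2:2 (counts {dict(counts)})"
            )
    p1, p2 = cross.parental_genotypes()
    parental = {(p1[ia], p1[ib]), (p2[ia], p2[ib])}
    observed = set(combos)
    if observed == parental:
        return "PD"
    if not observed & parental:
        return "NPD"
    return "TT"


@dataclass(frozen=True)
class TetradCounts:
    """PD/NPD/TT tallies for one marker pair."""

    pd: int
    npd: int
    tt: int
    marker_a: str = "a"
    marker_b: str = "b"
    per_octad: tuple[tuple[str, TetradClass], ...] = ()

    def __post_init__(self) -> None:
        if min(self.pd, self.npd, self.tt) < 0:
            raise ValueError("tetrad counts must be non-negative")

    @property
    def total(self) -> int:
        return self.pd + self.npd + self.tt


def tally_tetrads(
    table: OctadTable,
    marker_a: Union[str, MarkerDef],
    marker_b: Union[str, MarkerDef],
) -> TetradCounts:
    """Reduce every octad of *table* and tally PD/NPD/TT for a marker pair."""
    name_a = marker_a.name if isinstance(marker_a, MarkerDef) else marker_a
    name_b = marker_b.name if isinstance(marker_b, MarkerDef) else marker_b
    tallies = Counter()
    per_octad = []
    for octad in table.octads:
        tetrad = reduce_to_tetrad(octad)
        cls = classify_tetrad(tetrad, name_a, name_b, table.cross)
        tallies[cls] += 1
        per_octad.append((octad.ascus_id, cls))
    return TetradCounts(
        pd=tallies["PD"],
        npd=tallies["NPD"],
        tt=tallies["TT"],
        marker_a=name_a,
        marker_b=name_b,
        per_octad=tuple(per_octad),
    )


# ---------------------------------------------------------------------------
# linkage statistics


def perkins_distance(counts: TetradCounts) -> float:
    """Perkins map distance, 100 × (TT/2 + 3·NPD) / total, in centimorgans.

    The classical tetrad estimator; no interference correction is applied.
    """
    if counts.total == 0:
        raise ValueError("map distance is undefined for zero tetrads")
    return 100.0 * (counts.tt / 2.0 + 3.0 * counts.npd) / counts.total


@dataclass(frozen=True)
class LinkageTest:
    """PD-vs-NPD chi-square test of linkage (1 df).

    Under no linkage PD and NPD are equally frequent; an excess of PD
    indicates linkage.
    """

    chi2: float
    pvalue: float
    linked: bool
    alpha: float = 0.05


def linkage_test(counts: TetradCounts, alpha: float = 0.05) -> LinkageTest:
    """Chi-square test of PD = NPD with 1 degree of freedom."""
    n = counts.pd + counts.npd
    if n == 0:
        raise ValueError("linkage is untestable with zero ditype tetrads")
    chi2 = (counts.pd - counts.npd) ** 2 / n
    pvalue = float(stats.chi2.sf(chi2, df=1))
    return LinkageTest(chi2=float(chi2), pvalue=pvalue, linked=bool(pvalue < alpha), alpha=alpha)


# ---------------------------------------------------------------------------
# adjacent-pair discordance and orientation inference


@dataclass(frozen=True)
class DiscordanceResult:
    """Adjacent-pair discordance over the linear asci of a table.

    A pair of adjoining spores is discordant when their genotypes differ at
    one or more markers.  ``total_pairs`` is 4 × (included asci).
    """

    discordant_pairs: int
    total_pairs: int
    per_ascus: tuple[tuple[str, int], ...]
    excluded_asci: tuple[tuple[str, str], ...] = ()

    @property
    def fraction(self) -> float:
        return self.discordant_pairs / self.total_pairs if self.total_pairs else math.nan


def adjacent_discordance(table: OctadTable) -> DiscordanceResult:
    """Count discordant adjoining spore pairs (A,B), (C,D), (E,F), (G,H)
    over the linear asci of *table*.

    Dead spores take their sister-matching imputation; asci whose
    imputation is ambiguous, or which are not flagged linear, are excluded
    and listed with reasons.
    """
    per_ascus = []
    excluded = []
    for octad in table.octads:
        if not octad.linear:
            excluded.append((octad.ascus_id, "not a linear ascus"))
            continue
        pairing = match_sisters(octad)
        if pairing.ambiguous:
            excluded.append((octad.ascus_id, "ambiguous dead-spore imputation"))
            continue
        n_disc = sum(
            1
            for a, b in ADJACENT_PAIRS
            if pairing.genotypes[a] != pairing.genotypes[b]
        )
        per_ascus.append((octad.ascus_id, n_disc))
    if not per_ascus:
        raise StructureError("no linear asci available for discordance analysis")
    return DiscordanceResult(
        discordant_pairs=sum(n for _, n in per_ascus),
        total_pairs=4 * len(per_ascus),
        per_ascus=tuple(per_ascus),
        excluded_asci=tuple(excluded),
    )


@dataclass(frozen=True)
class OrientationVerdict:
    """Comparison of observed discordance against an arrangement-model null.

    ``null_mean`` is the null expectation of the discordant fraction;
    ``null_p`` the probability of observing at least the observed
    discordant-pair count under the model.
    """

    observed: DiscordanceResult
    model_name: str
    null_mean: float
    null_p: float
    reject: bool
    alpha: float = 0.05
    n_sims: int = 0


def orientation_test(
    observed: DiscordanceResult,
    model: str,
    config: Optional["SimConfig"] = None,  # noqa: F821 - forward ref to sim
    n_sims: int = 10000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> OrientationVerdict:
    """Test the observed discordance against an arrangement model.

    For ``linear_ordered`` (strictly ordered nuclei, mitotic daughters
    adjacent) the null is degenerate at zero discordance, so the test is
    exact: any observed discordant pair rejects strict order.  For
    stochastic models the null distribution of the discordant-pair count is
    estimated by simulating *n_sims* tables of the same size under
    *config*; the p-value is the upper-tail proportion (add-one
    Monte-Carlo estimate).
    """
    from . import sim as _sim  # deferred: analysis must not require sim at import

    if model == "linear_ordered":
        null_p = 0.0 if observed.discordant_pairs > 0 else 1.0
        return OrientationVerdict(
            observed=observed,
            model_name=model,
            null_mean=0.0,
            null_p=null_p,
            reject=observed.discordant_pairs > 0,
            alpha=alpha,
        )
    if model not in _sim.ARRANGEMENT_MODELS:
        raise ValueError(f"unknown arrangement model {model!r}")
    if config is None:
        raise ValueError(f"arrangement model {model!r} needs a SimConfig for its null")
    if n_sims < 1000:
        raise ValueError("simulation-based nulls need n_sims >= 1000")
    n_asci = len(observed.per_ascus)
    null_config = replace(
        config,
        arrangement=model,
        n_asci=n_asci,
        seed=config.seed if seed is None else seed,
    )
    counts = _sim.simulate_null_discordance(null_config, n_sims)
    null_mean = float(np.mean(counts)) / observed.total_pairs
    null_p = float((np.sum(counts >= observed.discordant_pairs) + 1) / (n_sims + 1))
    return OrientationVerdict(
        observed=observed,
        model_name=model,
        null_mean=null_mean,
        null_p=null_p,
        reject=bool(null_p < alpha),
        alpha=alpha,
        n_sims=n_sims,
    )


# ---------------------------------------------------------------------------
# iodine multilocus estimator


@dataclass(frozen=True)
class IodLociEstimate:
    """Unlinked-locus count behind an iodine-positive segregant fraction.

    Model: an iod+ segregant must inherit the iod+ parent's allele at all
    *n* unlinked loci, so the expected iod+ fraction is (1/2)^n.
    """

    fraction: float
    n_hat: float
    n_nearest: int
    expected_fraction: float


def iod_locus_estimate(iod_positive_fraction: float) -> IodLociEstimate:
    """Estimate the number of unlinked loci from an iod+ segregant fraction.

    Returns the continuous estimate n̂ = −log2(fraction), the nearest
    integer, and the expected fraction (1/2)^n at that integer.
    """
    f = float(iod_positive_fraction)
    if not 0.0 < f <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n_hat = -math.log2(f)
    n_nearest = round(n_hat)
    return IodLociEstimate(
        fraction=f,
        n_hat=n_hat,
        n_nearest=n_nearest,
        expected_fraction=0.5 ** n_nearest,
    )
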