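"""Forward simulation of a two-parent cross through meiosis, post-meiotic
mitosis, ascus packing, and spore viability.

Meiosis model
-------------
Crossovers follow the classical no-interference (Haldane) model: on each
chromosome arm the number of crossovers per four-chromatid bundle is
Poisson with mean 2·d (d = arm length in Morgans), each crossover joins
one uniformly chosen chromatid per homolog, and there is no chiasma or
chromatid interference.  Meiosis I segregates centromeres, meiosis II
segregates chromatids; two-locus recombination fractions therefore follow
the Haldane map function r = ½·(1 − e^(−2d)).

Rather than placing individual crossovers, the simulator propagates the
four chromatids' parental-origin vector from the centromere outward
marker-to-marker as the exact 6-state Markov jump process this crossover
model implies (crossover events at rate 2 per Morgan, each applying a
random homolog-0 × homolog-1 chromatid swap to the distal segment).  The
interval transition matrices are matrix exponentials of the single-swap
generator, so arbitrarily spaced markers are handled exactly and the whole
simulation is vectorised over meioses.

Ascus packing
-------------
The four meiotic nuclei are labelled (1a, 1b, 2a, 2b): meiosis I produces
nuclei 1 and 2, meiosis II splits each in two.  Each nucleus then divides
mitotically into two identical sister spores.  Four arrangement models map
nuclei to the eight ordered spore positions A–H:

- ``linear_ordered`` — both MII spindles in line, nucleus order
  (1a, 1b, 2a, 2b), mitotic daughters adjacent: sisters occupy
  (A,B), (C,D), (E,F), (G,H).
- ``parallel`` — MII spindles parallel (nucleus order 1a, 2a, 2b, 1b),
  daughters adjacent.
- ``random_nuclei`` — nuclei in random order, daughters adjacent.
- ``random_spores`` — all eight spores fully shuffled.

Reproducibility
---------------
Each ascus consumes a fixed budget of uniforms from a single PCG64 stream,
drawn row-wise, so ascus *i* of a run depends only on (seed, i): growing
``n_asci`` never reshuffles earlier asci, and identical (config, seed)
give identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.linalg import expm
from scipy.stats import poisson

from .analysis import ADJACENT_PAIRS, adjacent_discordance
from .io import (
    POSITIONS,
    UNKNOWN,
    CrossDef,
    Genotype,
    MarkerDef,
    Octad,
    OctadTable,
    SporeRecord,
)

__all__ = [
    "ARRANGEMENT_MODELS",
    "SimConfig",
    "TruthRecord",
    "SimulatedCross",
    "simulate_meiosis",
    "simulate_meioses",
    "pack_ascus",
    "simulate_cross",
    "simulate_octad_arrays",
    "simulate_null_discordance",
    "classify_product_origins",
    "haldane_r",
    "tetrad_class_probs",
    "expected_perkins",
]

ARRANGEMENT_MODELS = ("linear_ordered", "parallel", "random_nuclei", "random_spores")

# ---------------------------------------------------------------------------
# chromatid-origin Markov chain
#
# State: the parental origins of the four chromatids (two per homolog) at a
# point on the arm, e.g. (0, 0, 1, 1) at the centromere.  Chromatids 0, 1
# carry the homolog-0 centromere, chromatids 2, 3 the homolog-1 centromere.

STATES: tuple[tuple[int, ...], ...] = tuple(
    sorted(set(itertools.permutations((0, 0, 1, 1))))
)
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
_START = _STATE_INDEX[(0, 0, 1, 1)]
_STATES_ARR = np.array(STATES, dtype=np.int8)


def _single_swap_matrix() -> np.ndarray:
    """Transition matrix of one crossover: swap distal origins of one
    chromatid from each homolog, all four (i, j) choices equally likely."""
    S = np.zeros((6, 6))
    for si, s in enumerate(STATES):
        for i in (0, 1):
            for j in (2, 3):
                t = list(s)
                t[i], t[j] = t[j], t[i]
                S[si, _STATE_INDEX[tuple(t)]] += 0.25
    return S


_SWAP = _single_swap_matrix()


def _interval_matrix(d_morgans: float) -> np.ndarray:
    """Exact transition matrix across an interval of length *d* Morgans
    (Poisson(2d) crossovers, uniform chromatid choice)."""
    return expm(2.0 * d_morgans * (_SWAP - np.eye(6)))


# ---------------------------------------------------------------------------
# per-cross layout: marker grouping by arm and the per-ascus uniform budget


@dataclass(frozen=True)
class _Layout:
    chromosomes: tuple[str, ...]
    groups: tuple[tuple[int, ...], ...]       # marker indices per (chrom, arm)
    group_chrom: tuple[int, ...]              # chromosome index per group
    group_cum: tuple[tuple[np.ndarray, ...], ...]  # cumulative P rows per step
    chain_col: tuple[int, ...]                # uniform column per marker index
    seg_col0: int
    arr_col0: int
    via_col0: int
    budget: int


def _layout(cross: CrossDef) -> _Layout:
    markers = cross.markers
    chromosomes = tuple(sorted({m.chromosome for m in markers}))
    chrom_index = {c: i for i, c in enumerate(chromosomes)}
    groups: list[tuple[int, ...]] = []
    group_chrom: list[int] = []
    group_cum: list[tuple[np.ndarray, ...]] = []
    chain_col = [0] * len(markers)
    col = 0
    for chrom in chromosomes:
        for arm in ("left", "right"):
            idx = [
                i
                for i, m in enumerate(markers)
                if m.chromosome == chrom and m.arm == arm
            ]
            if not idx:
                continue
            idx.sort(key=lambda i: (markers[i].position_cM, markers[i].name))
            groups.append(tuple(idx))
            group_chrom.append(chrom_index[chrom])
            cums = []
            prev = 0.0
            for i in idx:
                gap = (markers[i].position_cM - prev) / 100.0
                P = _interval_matrix(gap)
                cum = np.cumsum(P, axis=1)
                cum[:, -1] = 1.0
                cums.append(cum)
                prev = markers[i].position_cM
                chain_col[i] = col
                col += 1
            group_cum.append(tuple(cums))
    seg_col0 = col
    arr_col0 = seg_col0 + 3 * len(chromosomes)
    via_col0 = arr_col0 + 8
    return _Layout(
        chromosomes=chromosomes,
        groups=tuple(groups),
        group_chrom=tuple(group_chrom),
        group_cum=tuple(group_cum),
        chain_col=tuple(chain_col),
        seg_col0=seg_col0,
        arr_col0=arr_col0,
        via_col0=via_col0,
        budget=via_col0 + 8,
    )


# ---------------------------------------------------------------------------
# vectorised meiosis


def _products_from_uniforms(
    cross: CrossDef, U: np.ndarray, layout: _Layout
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one meiosis per row of *U*.

    Returns ``(product_origin, sds)``: parental origin (0 = parent 1,
    1 = parent 2) of each marker in each of the four meiotic nuclei
    (1a, 1b, 2a, 2b), shape (n, 4, n_markers); and per-marker
    second-division-segregation flags, shape (n, n_markers).
    """
    n = U.shape[0]
    n_markers = len(cross.markers)
    product_origin = np.empty((n, 4, n_markers), dtype=np.int8)
    sds = np.empty((n, n_markers), dtype=bool)

    # chromatid -> nucleus assignment per chromosome: a coin chooses which
    # homolog's centromere pair goes to MI pole 1, two more order the
    # chromatids within each MII division
    perms = []
    rows = np.arange(n)[:, None]
    for k in range(len(layout.chromosomes)):
        uc, uo1, uo2 = (U[:, layout.seg_col0 + 3 * k + j] for j in range(3))
        first = np.where(uc < 0.5, 0, 2).astype(np.int8)
        second = (2 - first).astype(np.int8)
        o1 = (uo1 < 0.5).astype(np.int8)
        o2 = (uo2 < 0.5).astype(np.int8)
        perm = np.empty((n, 4), dtype=np.int8)
        perm[:, 0] = first + o1
        perm[:, 1] = first + 1 - o1
        perm[:, 2] = second + o2
        perm[:, 3] = second + 1 - o2
        perms.append(perm)

    for g, idx in enumerate(layout.groups):
        perm = perms[layout.group_chrom[g]]
        cur = np.full(n, _START, dtype=np.intp)
        for step, m in enumerate(idx):
            cum = layout.group_cum[g][step]
            u = U[:, layout.chain_col[m]]
            cur = np.minimum((u[:, None] > cum[cur]).sum(axis=1), 5).astype(np.intp)
            orig = _STATES_ARR[cur]  # (n, 4) origins by chromatid
            sds[:, m] = orig[:, 0] != orig[:, 1]
            product_origin[:, :, m] = np.take_along_axis(orig, perm, axis=1)
    return product_origin, sds


def simulate_meioses(
    cross: CrossDef, n: int, rng: Union[int, np.random.Generator, None] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate *n* independent meioses of *cross*.

    Returns ``(product_origin, sds)`` as in the module description:
    parental origins, shape (n, 4, n_markers), nuclei ordered
    (1a, 1b, 2a, 2b); and SDS flags, shape (n, n_markers).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    layout = _layout(cross)
    U = rng.random((n, layout.arr_col0))  # chain + segregation budget only
    return _products_from_uniforms(cross, U, layout)


def _origin_to_genotypes(cross: CrossDef, origin: np.ndarray) -> list[Genotype]:
    """Map origin vectors (..., n_markers) of 0/1 to allele-symbol tuples."""
    alleles = [(m.allele_p1, m.allele_p2) for m in cross.markers]
    flat = origin.reshape(-1, origin.shape[-1])
    out = [
        tuple(alleles[j][int(o)] for j, o in enumerate(row)) for row in flat
    ]
    return out


def simulate_meiosis(
    cross: CrossDef, rng: Union[int, np.random.Generator, None] = None
) -> tuple[tuple[Genotype, ...], dict[str, bool]]:
    """Single-meiosis convenience wrapper.

    Returns the four product genotypes (nuclei 1a, 1b, 2a, 2b) and a
    per-marker second-division-segregation flag map.
    """
    origin, sds = simulate_meioses(cross, 1, rng)
    products = tuple(_origin_to_genotypes(cross, origin[0]))
    flags = {m.name: bool(sds[0, j]) for j, m in enumerate(cross.markers)}
    return products, flags


# ---------------------------------------------------------------------------
# ascus packing

# copy c (0..7) is spore copy c % 2 of nucleus c // 2
_LINEAR_COPIES = np.arange(8)
_PARALLEL_COPIES = np.array([0, 1, 4, 5, 6, 7, 2, 3])  # nuclei (1a, 2a, 2b, 1b)


def _copies_at_positions(
    model: str, n: int, U8: np.ndarray
) -> np.ndarray:
    """Spore-copy id occupying each of the 8 positions, shape (n, 8)."""
    if model == "linear_ordered":
        return np.broadcast_to(_LINEAR_COPIES, (n, 8))
    if model == "parallel":
        return np.broadcast_to(_PARALLEL_COPIES, (n, 8))
    if model == "random_nuclei":
        order = np.argsort(U8[:, :4], axis=1)  # random nucleus order
        copies = np.empty((n, 8), dtype=np.intp)
        copies[:, 0::2] = 2 * order
        copies[:, 1::2] = 2 * order + 1
        return copies
    if model == "random_spores":
        return np.argsort(U8, axis=1)  # uniform permutation of all 8 copies
    raise ValueError(f"unknown arrangement model {model!r}")


def pack_ascus(
    products: Sequence[Genotype],
    model: str,
    rng: Union[int, np.random.Generator, None] = None,
) -> tuple[tuple[Genotype, ...], tuple[tuple[str, str], ...]]:
    """Pack four meiotic product genotypes into an ordered 8-spore ascus.

    Returns the spore genotypes at positions A–H and the sister map: for
    each product, the pair of positions holding its two mitotic daughters.
    """
    if len(products) != 4:
        raise ValueError("an ascus packs exactly 4 meiotic products")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    copies = _copies_at_positions(model, 1, rng.random((1, 8)))[0]
    spores = tuple(tuple(products[c // 2]) for c in copies)
    pos_of_copy = np.argsort(copies)
    sisters = tuple(
        tuple(sorted((POSITIONS[pos_of_copy[2 * p]], POSITIONS[pos_of_copy[2 * p + 1]])))
        for p in range(4)
    )
    return spores, sisters


# ---------------------------------------------------------------------------
# full cross simulation


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated cross.

    ``viability`` is the per-spore survival probability; dead spores are
    emitted with unknown genotypes in the observed table (their true
    genotypes live in the truth channel).
    """

    cross: CrossDef
    n_asci: int
    arrangement: str = "linear_ordered"
    viability: float = 1.0
    seed: int = 0
    emit_truth: bool = False

    def __post_init__(self) -> None:
        if self.n_asci < 1:
            raise ValueError("n_asci must be >= 1")
        if not 0.0 <= self.viability <= 1.0:
            raise ValueError("viability must be in [0, 1]")
        if self.arrangement not in ARRANGEMENT_MODELS:
            raise ValueError(
                f"unknown arrangement model {self.arrangement!r}; "
                f"choose from {ARRANGEMENT_MODELS}"
            )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated ascus: the four meiotic product
    genotypes (nuclei 1a, 1b, 2a, 2b), the sister-pair position map, and
    per-marker second-division-segregation flags."""

    ascus_id: str
    products: tuple[Genotype, Genotype, Genotype, Genotype]
    sister_pairs: tuple[tuple[str, str], ...]
    sds: dict[str, bool]


@dataclass(frozen=True)
class SimulatedCross:
    """Output of :func:`simulate_cross`: the observed octad table and,
    when requested, the per-ascus truth channel."""

    table: OctadTable
    truth: Optional[tuple[TruthRecord, ...]] = None


def simulate_octad_arrays(
    config: SimConfig, n: Optional[int] = None
) -> dict[str, np.ndarray]:
    """Array-level simulation backend (fast path).

    Returns a dict with ``spore_origin`` (n, 8, M) parental origins per
    ordered spore position, ``spore_product`` (n, 8) meiotic-product index
    per position, ``product_origin`` (n, 4, M), ``sds`` (n, M), ``dead``
    (n, 8), and ``pos_of_copy`` (n, 8).  Deterministic in (config.seed, n);
    row i is invariant to n.
    """
    n = config.n_asci if n is None else n
    layout = _layout(config.cross)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    U = rng.random((n, layout.budget))
    product_origin, sds = _products_from_uniforms(config.cross, U, layout)
    copies = _copies_at_positions(
        config.arrangement, n, U[:, layout.arr_col0 : layout.arr_col0 + 8]
    )
    rows = np.arange(n)[:, None]
    spore_product = copies // 2
    spore_origin = product_origin[rows, spore_product, :]
    if config.viability >= 1.0:
        dead = np.zeros((n, 8), dtype=bool)
    else:
        dead = U[:, layout.via_col0 : layout.via_col0 + 8] >= config.viability
    return {
        "spore_origin": spore_origin,
        "spore_product": spore_product,
        "product_origin": product_origin,
        "sds": sds,
        "dead": dead,
        "pos_of_copy": np.argsort(copies, axis=1),
    }


def simulate_cross(config: SimConfig) -> SimulatedCross:
    """Simulate a full cross into an :class:`~octadkit.io.OctadTable`.

    Reproducible: identical (config, seed) give identical tables, and the
    first k asci do not change when ``n_asci`` grows.
    """
    arrays = simulate_octad_arrays(config)
    cross = config.cross
    alleles = [(m.allele_p1, m.allele_p2) for m in cross.markers]
    unknown = tuple(UNKNOWN for _ in cross.markers)
    octads = []
    truths = []
    for i in range(config.n_asci):
        ascus_id = str(i + 1)
        spores = []
        for pos_idx, pos in enumerate(POSITIONS):
            origin = arrays["spore_origin"][i, pos_idx]
            genotype = tuple(alleles[j][int(o)] for j, o in enumerate(origin))
            is_dead = bool(arrays["dead"][i, pos_idx])
            spores.append(
                SporeRecord(
                    ascus_id=ascus_id,
                    position=pos,
                    viable=not is_dead,
                    genotype=unknown if is_dead else genotype,
                )
            )
        octads.append(Octad(ascus_id=ascus_id, spores=tuple(spores), linear=True))
        if config.emit_truth:
            prod_geno = tuple(
                tuple(alleles[j][int(o)] for j, o in enumerate(arrays["product_origin"][i, p]))
                for p in range(4)
            )
            pos_of_copy = arrays["pos_of_copy"][i]
            sisters = tuple(
                tuple(
                    sorted(
                        (POSITIONS[pos_of_copy[2 * p]], POSITIONS[pos_of_copy[2 * p + 1]])
                    )
                )
                for p in range(4)
            )
            truths.append(
                TruthRecord(
                    ascus_id=ascus_id,
                    products=prod_geno,  # type: ignore[arg-type]
                    sister_pairs=sisters,
                    sds={
                        m.name: bool(arrays["sds"][i, j])
                        for j, m in enumerate(cross.markers)
                    },
                )
            )
    table = OctadTable(cross=cross, octads=tuple(octads))
    return SimulatedCross(table=table, truth=tuple(truths) if config.emit_truth else None)


def simulate_null_discordance(config: SimConfig, n_sims: int) -> np.ndarray:
    """Null distribution of the per-table discordant-adjacent-pair count.

    Simulates *n_sims* independent tables of ``config.n_asci`` asci under
    the configured arrangement model and returns the discordant-pair count
    of each (shape ``(n_sims,)``).  Fully viable configs run on the array
    fast path; with viability < 1 each table goes through the full
    imputation pipeline (ambiguous asci excluded, as in the estimator).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if config.viability >= 1.0:
        arrays = simulate_octad_arrays(config, n=n_sims * config.n_asci)
        so = arrays["spore_origin"]
        concordant = (so[:, 0::2, :] == so[:, 1::2, :]).all(axis=2)  # (n, 4)
        disc = 4 - concordant.sum(axis=1)
        return disc.reshape(n_sims, config.n_asci).sum(axis=1)
    counts = np.empty(n_sims, dtype=np.int64)
    for s in range(n_sims):
        cfg = SimConfig(
            cross=config.cross,
            n_asci=config.n_asci,
            arrangement=config.arrangement,
            viability=config.viability,
            seed=config.seed + s,
        )
        result = adjacent_discordance(simulate_cross(cfg).table)
        counts[s] = result.discordant_pairs
    return counts


def classify_product_origins(
    product_origin: np.ndarray, ia: int, ib: int
) -> tuple[int, int, int]:
    """PD/NPD/TT tallies for a marker pair straight from origin arrays.

    A product is parental for the pair when both loci share the same
    parental origin.  Array twin of the object pipeline
    (:func:`octadkit.analysis.tally_tetrads`), used for large simulation
    studies; a unit test pins the two routes together.
    """
    parental = product_origin[:, :, ia] == product_origin[:, :, ib]
    k = parental.sum(axis=1)
    pd_ = int(np.sum(k == 4))
    npd = int(np.sum(k == 0))
    tt = int(np.sum((k != 4) & (k != 0)))
    return pd_, npd, tt


# ---------------------------------------------------------------------------
# Haldane-model theory (closed forms used as oracles and expectations)


def haldane_r(d_cM: float) -> float:
    """Haldane map function: recombination fraction at map distance d."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


# one-crossover transition between tetrad classes for an interval
# (PD, NPD, TT) x (PD, NPD, TT); derived from the chromatid-swap chain
_CLASS_STEP = np.array(
    [
        [0.0, 0.0, 1.0],
        [0.0, 0.0, 1.0],
        [0.25, 0.25, 0.5],
    ]
)


def tetrad_class_probs(d_cM: float, tail: float = 1e-12) -> dict[str, float]:
    """Exact PD/NPD/TT probabilities at map distance *d* under the
    no-interference model (Poisson(2d) crossovers, no chromatid
    interference), computed by mixing the per-crossover class chain over
    the Poisson crossover count."""
    mean = 2.0 * d_cM / 100.0
    v = np.array([1.0, 0.0, 0.0])
    probs = np.zeros(3)
    k = 0
    while True:
        w = poisson.pmf(k, mean)
        probs += w * v
        if k > mean and poisson.sf(k, mean) < tail:
            break
        v = v @ _CLASS_STEP
        k += 1
    return {"PD": float(probs[0]), "NPD": float(probs[1]), "TT": float(probs[2])}


def expected_perkins(d_cM: float) -> float:
    """Expected Perkins estimate at true separation *d* cM under the
    Haldane model (biased low at large d; the bias is a property of the
    estimator, not an implementation artifact)."""
    p = tetrad_class_probs(d_cM)
    return 100.0 * (p["TT"] / 2.0 + 3.0 * p["NPD"])
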