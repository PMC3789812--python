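"""Orchestration: end-to-end reproduction of the packaged linear-ascus
analysis and configurable simulation studies, with run manifests.

The packaged fixture is the nine-ascus linear-octad genotype table of the
Sjk10 × Sjk19 cross (four markers: mat1, ade6, ura4, mrc1) together with
its cross definition.  :func:`reproduce_paper` runs the complete analysis
chain on it — Mendelian 4:4 checks, dead-spore imputation, pairwise tetrad
tallies, adjacent-pair discordance, arrangement-model verdicts, the
linkage statistics for the reported 38 PD : 7 NPD : 39 TT mat1–mrc1 tally,
and the iodine multilocus estimate for the reported 12.3% iod+ segregant
fraction — and emits a machine-first TSV report plus a manifest sufficient
to re-execute the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import analysis, growth, sim
from .io import (
    CrossDef,
    OctadTable,
    is_four_four,
    read_cross_config,
    read_octad_table,
    segregation_counts,
)

__all__ = [
    "FIXTURE_TABLE",
    "FIXTURE_CROSS",
    "REPORTED_MAT1_MRC1_COUNTS",
    "REPORTED_IOD_POSITIVE_FRACTION",
    "RunManifest",
    "PaperReport",
    "fixture_path",
    "load_fixture_cross",
    "load_fixture_table",
    "reproduce_paper",
    "run_simulation_study",
    "study_discordance_null",
    "study_perkins_recovery",
    "study_type1_error",
    "study_growth_recovery",
]

FIXTURE_TABLE = "table2_octads.tsv"
FIXTURE_CROSS = "cross_sjk10_x_sjk19.cfg"

# published tallies from the source cross (inputs to the linkage statistics,
# not outputs of this package)
REPORTED_MAT1_MRC1_COUNTS = analysis.TetradCounts(
    pd=38, npd=7, tt=39, marker_a="mat1", marker_b="mrc1"
)
REPORTED_IOD_POSITIVE_FRACTION = 0.123

_FIXTURE_SHA256 = {
    FIXTURE_TABLE: "5082ebca08be73ea26fae1b6b21d5d9e3cba368ab6ac60321d0e90d5543d7f7b",
    FIXTURE_CROSS: "53f536cce41e1ca360dce52cadf79149c0b0ad2a28a820fb1e79cc98264d17b9",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    return Path(str(resources.files("octadkit").joinpath("data", name)))


def _digest(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _verify_fixtures() -> dict[str, str]:
    digests = {}
    for name, expected in _FIXTURE_SHA256.items():
        got = _digest(fixture_path(name))
        if got != expected:
            raise RuntimeError(
                f"fixture {name} digest mismatch: expected {expected}, got {got}"
            )
        digests[name] = got
    return digests


def load_fixture_cross() -> CrossDef:
    """The packaged Sjk10 × Sjk19 cross definition."""
    return read_cross_config(fixture_path(FIXTURE_CROSS))


def load_fixture_table(cross: Optional[CrossDef] = None) -> OctadTable:
    """The packaged nine-ascus linear-octad genotype table."""
    return read_octad_table(fixture_path(FIXTURE_TABLE), cross or load_fixture_cross())


# ---------------------------------------------------------------------------
# run manifests


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to re-execute a run bit-identically (for
    deterministic commands): command, config hash, seeds, package version,
    input digests, timestamp."""

    command: str
    config_hash: str
    seeds: dict[str, int]
    version: str
    input_digests: dict[str, str]
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _make_manifest(
    command: str,
    config: Any,
    seeds: dict[str, int],
    input_digests: dict[str, str],
) -> RunManifest:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return RunManifest(
        command=command,
        config_hash=hashlib.sha256(blob).hexdigest(),
        seeds=seeds,
        version=__version__,
        input_digests=input_digests,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


# ---------------------------------------------------------------------------
# paper reproduction


@dataclass(frozen=True)
class PaperReport:
    """Structured output of :func:`reproduce_paper`.

    ``rows`` is the machine-first report (name, value, n, p, notes);
    ``ok`` is True when every internal validation passed.
    """

    rows: tuple[dict[str, Any], ...]
    manifest: RunManifest
    ok: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["name", "value", "n", "p", "notes"])

    def value(self, name: str) -> Any:
        for row in self.rows:
            if row["name"] == name:
                return row["value"]
        raise KeyError(name)


def reproduce_paper(
    n_sims: int = 10000, seed: int = 0, out_dir: Optional[Union[str, Path]] = None
) -> PaperReport:
    """Run the full analysis chain on the packaged fixture.

    Emits per-marker 4:4 checks, imputed dead-spore genotypes, all pairwise
    tetrad tallies, the 21-of-36 adjacent-pair discordance with per-ascus
    breakdown, orientation verdicts against the strictly ordered and fully
    shuffled arrangement models, Perkins distance and chi-square for the
    reported mat1–mrc1 (38, 7, 39) tally, and the iodine multilocus
    estimate for the reported 12.3% fraction.
    """
    digests = _verify_fixtures()
    cross = load_fixture_cross()
    table = load_fixture_table(cross)
    rows: list[dict[str, Any]] = []
    ok = True

    def add(name, value, n=None, p=None, notes=""):
        rows.append({"name": name, "value": value, "n": n, "p": p, "notes": notes})

    # Mendelian 4:4 checks after imputation
    all_4to4 = True
    imputed_octads = [analysis.impute_octad(o) for o in table.octads]
    for octad in imputed_octads:
        for marker in cross.markers:
            counts = segregation_counts(octad, marker, cross)
            if not is_four_four(counts):
                all_4to4 = False
        matP = segregation_counts(octad, "mat1", cross).get("P", 0)
        add(f"mat1_P_count[ascus {octad.ascus_id}]", matP, n=8,
            notes="P-allele count among the 8 spores")
    add("all_markers_4to4", int(all_4to4), n=len(table.octads) * len(cross.markers),
        notes="every marker segregates 4:4 in every octad after imputation")
    ok &= all_4to4

    # dead-spore imputations
    n_imputed = 0
    for octad in table.octads:
        pairing = analysis.match_sisters(octad)
        for pos, genotype in pairing.imputed:
            add(f"imputed[ascus {octad.ascus_id}:{pos}]", " ".join(genotype),
                notes="dead-spore genotype deduced by sister matching")
            n_imputed += 1
    add("imputed_spores", n_imputed, n=len(table.octads))

    # pairwise tetrad tallies from the fixture
    names = cross.marker_names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            counts = analysis.tally_tetrads(table, a, b)
            add(f"tetrads[{a}-{b}]", f"{counts.pd}:{counts.npd}:{counts.tt}",
                n=counts.total, notes="PD:NPD:TT")
            if counts.pd + counts.npd > 0:
                test = analysis.linkage_test(counts)
                add(f"perkins_cM[{a}-{b}]",
                    round(analysis.perkins_distance(counts), 2), n=counts.total)
                add(f"chi2[{a}-{b}]", round(test.chi2, 3), n=counts.total,
                    p=test.pvalue)

    # adjacent-pair discordance and orientation verdicts
    disc = analysis.adjacent_discordance(table)
    add("discordant_pairs", disc.discordant_pairs, n=disc.total_pairs,
        notes="adjoining spore pairs differing at >=1 marker")
    for ascus_id, n_disc in disc.per_ascus:
        add(f"discordant[ascus {ascus_id}]", n_disc, n=4)
    config = sim.SimConfig(cross=cross, n_asci=len(disc.per_ascus), seed=seed)
    for model in ("linear_ordered", "random_spores"):
        verdict = analysis.orientation_test(
            disc, model, config=config, n_sims=n_sims, seed=seed
        )
        add(f"orientation[{model}]", "reject" if verdict.reject else "consistent",
            n=verdict.n_sims or None, p=verdict.null_p,
            notes=f"null mean discordant fraction {verdict.null_mean:.3f}")
    ok &= disc.total_pairs == 4 * len(disc.per_ascus)

    # linkage statistics on the reported mat1-mrc1 tally
    rep = REPORTED_MAT1_MRC1_COUNTS
    test = analysis.linkage_test(rep)
    add("reported_tetrads[mat1-mrc1]", f"{rep.pd}:{rep.npd}:{rep.tt}", n=rep.total,
        notes="published tally, input")
    add("perkins_cM[reported mat1-mrc1]", round(analysis.perkins_distance(rep), 2),
        n=rep.total)
    add("chi2[reported mat1-mrc1]", round(test.chi2, 3), n=rep.total, p=test.pvalue,
        notes="linked" if test.linked else "unlinked")

    # iodine multilocus estimate
    est = analysis.iod_locus_estimate(REPORTED_IOD_POSITIVE_FRACTION)
    add("iod_locus_estimate", round(est.n_hat, 2),
        notes=f"nearest integer {est.n_nearest}, "
              f"expected fraction {100 * est.expected_fraction:.1f}%")

    manifest = _make_manifest(
        command="reproduce-paper",
        config={"n_sims": n_sims, "seed": seed},
        seeds={"seed": seed},
        input_digests=digests,
    )
    report = PaperReport(rows=tuple(rows), manifest=manifest, ok=ok)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(manifest.to_json())
    return report


# ---------------------------------------------------------------------------
# simulation studies


def _two_marker_cross(d_cM: float, linked: bool = True) -> CrossDef:
    """A minimal cross with two markers either *d* cM apart on one arm or
    centromere-linked on separate chromosomes (unlinked)."""
    from .io import MarkerDef

    if linked:
        markers = (
            MarkerDef("locA", "chr1", "left", 0.0, "A", "a"),
            MarkerDef("locB", "chr1", "left", d_cM, "B", "b"),
        )
    else:
        markers = (
            MarkerDef("locA", "chr1", "left", 0.0, "A", "a"),
            MarkerDef("locB", "chr2", "left", 0.0, "B", "b"),
        )
    return CrossDef(markers=markers)


def study_discordance_null(
    cross: CrossDef,
    model: str,
    n_asci: int,
    n_sims: int,
    seed: int = 0,
    viability: float = 1.0,
) -> dict[str, Any]:
    """Empirical null of the discordant-pair count for one arrangement model."""
    config = sim.SimConfig(
        cross=cross, n_asci=n_asci, arrangement=model, viability=viability, seed=seed
    )
    counts = sim.simulate_null_discordance(config, n_sims)
    return {
        "model": model,
        "n_asci": n_asci,
        "n_sims": n_sims,
        "mean_discordant": float(np.mean(counts)),
        "sd_discordant": float(np.std(counts, ddof=1)) if n_sims > 1 else 0.0,
        "max_discordant": int(np.max(counts)),
        "mean_fraction": float(np.mean(counts)) / (4 * n_asci),
    }


def study_perkins_recovery(
    distances_cM: Sequence[float],
    n_tetrads: int = 2000,
    n_reps: int = 25,
    seed: int = 0,
) -> list[dict[str, Any]]:
    """Mean Perkins estimate over replicate simulated tetrad samples,
    against the Haldane-implied expectation at each true distance."""
    out = []
    for d in distances_cM:
        cross = _two_marker_cross(d)
        rng = np.random.default_rng(seed)
        estimates = []
        for _ in range(n_reps):
            origin, _sds = sim.simulate_meioses(cross, n_tetrads, rng)
            pd_, npd, tt = sim.classify_product_origins(origin, 0, 1)
            counts = analysis.TetradCounts(pd=pd_, npd=npd, tt=tt)
            estimates.append(analysis.perkins_distance(counts))
        expected = sim.expected_perkins(d)
        out.append(
            {
                "true_cM": float(d),
                "expected_cM": expected,
                "mean_estimate_cM": float(np.mean(estimates)),
                "sd_estimate_cM": float(np.std(estimates, ddof=1)) if n_reps > 1 else 0.0,
                "n_tetrads": n_tetrads,
                "n_reps": n_reps,
            }
        )
    return out


def study_type1_error(
    n_asci: int = 100, n_reps: int = 400, alpha: float = 0.05, seed: int = 0
) -> dict[str, Any]:
    """Rejection rate of the PD-vs-NPD linkage test on unlinked markers."""
    cross = _two_marker_cross(0.0, linked=False)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        origin, _sds = sim.simulate_meioses(cross, n_asci, rng)
        pd_, npd, tt = sim.classify_product_origins(origin, 0, 1)
        counts = analysis.TetradCounts(pd=pd_, npd=npd, tt=tt)
        if analysis.linkage_test(counts, alpha=alpha).linked:
            rejections += 1
    rate = rejections / n_reps
    return {
        "n_asci": n_asci,
        "n_reps": n_reps,
        "alpha": alpha,
        "rejection_rate": rate,
        "se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }


def study_growth_recovery(
    doubling_times: Sequence[float] = (63.0, 93.0),
    noise_sd: float = 0.02,
    n_seeds: int = 100,
    seed: int = 0,
) -> list[dict[str, Any]]:
    """Doubling-time recovery from synthetic noisy curves."""
    out = []
    for truth in doubling_times:
        recovered = []
        for k in range(n_seeds):
            curve = growth.simulate_growth(
                doubling_time=truth, noise_sd=noise_sd, seed=seed * n_seeds + k
            )
            recovered.append(growth.fit_doubling_time(curve).doubling_time)
        mean = float(np.mean(recovered))
        out.append(
            {
                "true_min": float(truth),
                "mean_recovered_min": mean,
                "sd_recovered_min": float(np.std(recovered, ddof=1)),
                "relative_error": abs(mean - truth) / truth,
                "noise_sd": noise_sd,
                "n_seeds": n_seeds,
            }
        )
    return out


def run_simulation_study(
    config: Union[str, Path, dict], out_dir: Union[str, Path]
) -> dict[str, pd.DataFrame]:
    """Execute the studies declared in a YAML config and write TSV
    summaries plus a manifest to *out_dir*.

    The config maps ``seed`` (default 0) and ``studies`` to a list of
    study declarations, each with a ``kind`` of ``discordance_null``,
    ``perkins_recovery``, ``type1_error`` or ``growth_recovery`` plus that
    study's parameters.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        doc = yaml.safe_load(config_path.read_text())
        digests = {str(config_path): _digest(config_path)}
    else:
        doc = dict(config)
        digests = {}
    if not isinstance(doc, dict) or not isinstance(doc.get("studies"), list):
        raise ValueError("study config must map 'studies' to a list")
    base_seed = int(doc.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    for k, study in enumerate(doc["studies"]):
        kind = study.get("kind")
        seed = int(study.get("seed", base_seed))
        if kind == "discordance_null":
            cross = (
                read_cross_config(study["cross"])
                if "cross" in study
                else load_fixture_cross()
            )
            rows = [
                study_discordance_null(
                    cross,
                    model=study.get("model", "random_spores"),
                    n_asci=int(study.get("n_asci", 9)),
                    n_sims=int(study.get("n_sims", 1000)),
                    seed=seed,
                    viability=float(study.get("viability", 1.0)),
                )
            ]
        elif kind == "perkins_recovery":
            rows = study_perkins_recovery(
                distances_cM=study.get("distances_cM", [5, 10, 20, 30]),
                n_tetrads=int(study.get("n_tetrads", 2000)),
                n_reps=int(study.get("n_reps", 25)),
                seed=seed,
            )
        elif kind == "type1_error":
            rows = [
                study_type1_error(
                    n_asci=int(study.get("n_asci", 100)),
                    n_reps=int(study.get("n_reps", 400)),
                    alpha=float(study.get("alpha", 0.05)),
                    seed=seed,
                )
            ]
        elif kind == "growth_recovery":
            rows = study_growth_recovery(
                doubling_times=study.get("doubling_times", [63.0, 93.0]),
                noise_sd=float(study.get("noise_sd", 0.02)),
                n_seeds=int(study.get("n_seeds", 100)),
                seed=seed,
            )
        else:
            raise ValueError(f"unknown study kind {kind!r}")
        frame = pd.DataFrame(rows)
        name = f"{k:02d}_{kind}"
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        results[name] = frame
    manifest = _make_manifest(
        command="study", config=doc, seeds={"seed": base_seed}, input_digests=digests
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return results
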