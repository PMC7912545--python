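"""End-to-end orchestration: simulate/ingest -> demography -> diversity ->
gene origin -> structure -> CDA, from a single config with one seed.

Every stochastic component receives a seed derived from ``RunConfig.seed``,
so identical configs produce byte-identical numeric outputs; a manifest
records versions, the seed, per-stage wall-clock and per-stage record
counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, cda, demography, gene_origin, io, relatedness, simulate, structure

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration.

    Either ``input_path`` (pedigree CSV) or ``simulation`` (a dict with the
    fields of :class:`pedstruct.simulate.SimulationConfig`, simulated as a
    two-breed composite) must be given.
    """

    input_path: str | None = None
    simulation: dict | None = None
    selector: str = "historical"         # historical | current | breed label
    out_dir: str = "pedstruct_run"
    seed: int = 0
    run_demography: bool = True
    run_diversity: bool = True
    run_gene_origin: bool = True
    run_structure: bool = True
    run_cda: bool = True
    vif_threshold: float = cda.DEFAULT_VIF_THRESHOLD
    f_to_enter: float = cda.DEFAULT_F_TO_ENTER
    priors: str = "from_group_sizes"

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("give exactly one of input_path or simulation")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages and write all artifacts to ``cfg.out_dir``.

    Returns the in-memory artifacts keyed by stage name.  Any stage failure
    is re-raised with the stage name attached.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(cfg), indent=2))

    artifacts: dict = {}
    manifest: dict = {
        "pedstruct_version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "checksums": {},
    }

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 4)}
        return result

    def load():
        if cfg.input_path:
            ped = io.read_pedigree(cfg.input_path)
        else:
            sim = dict(cfg.simulation or {})
            sim.setdefault("seed", cfg.seed)
            sc = simulate.SimulationConfig(**sim)
            ped, _ = simulate.simulate_composite(sc, dataclasses.replace(sc), seed=cfg.seed)
        return io.subset_population(ped, cfg.selector)

    ped = stage("load", load)
    manifest["stages"]["load"]["n_animals"] = len(ped)
    manifest["stages"]["load"]["n_focal"] = int(ped.focal.sum())
    artifacts["pedigree"] = ped

    if cfg.run_demography:
        def demo():
            comp = demography.completeness(ped)
            intervals = demography.generation_intervals(ped)
            return {"completeness": comp, "intervals": intervals}
        artifacts["demography"] = stage("demography", demo)
        manifest["stages"]["demography"]["n_undated_links"] = artifacts["demography"][
            "intervals"
        ].n_undated_links
        io.write_report(artifacts["demography"]["intervals"], out / "intervals.json")

    if cfg.run_diversity:
        summary = stage(
            "diversity", lambda: relatedness.diversity_summary(ped, seed=cfg.seed)
        )
        artifacts["diversity"] = summary
        per = summary.per_individual
        per.to_csv(out / "diversity_per_individual.csv")
        pop = {k: v for k, v in dataclasses.asdict(summary).items() if k != "per_individual"}
        io.write_report(pop, out / "diversity.json")

    if cfg.run_gene_origin:
        report = stage("gene_origin", lambda: gene_origin.gene_origin_report(ped))
        artifacts["gene_origin"] = report
        io.write_report(report, out / "gene_origin.json")

    if cfg.run_structure:
        rep = stage("structure", lambda: structure.structure_report(ped, seed=cfg.seed))
        artifacts["structure"] = rep
        rep.nei_matrix.to_csv(out / "nei_distances.csv")
        (out / "upgma.nwk").write_text(rep.newick + "\n")
        io.write_report(
            {
                "ne_f": rep.ne_f,
                "ne_c": rep.ne_c,
                "equivalent_subpopulations": rep.s,
                "f_statistics": rep.f_statistics,
            },
            out / "structure.json",
        )

    if cfg.run_cda:
        def run_cda():
            X, groups = cda.assemble_features(ped)
            retained, vif_table, removed = cda.vif_screen(X, threshold=cfg.vif_threshold)
            model = cda.fit_cda(X[retained], groups, priors=cfg.priors)
            report = cda.classify_loocv(X[retained], groups, priors=cfg.priors)
            coords = cda.territorial_coordinates(model, X[retained], groups)
            return {
                "model": model,
                "classification": report,
                "vif": vif_table,
                "vif_removed": removed,
                "territorial": coords,
            }
        res = stage("cda", run_cda)
        artifacts["cda"] = res
        res["classification"].confusion.to_csv(out / "confusion.csv")
        res["classification"].loocv_confusion.to_csv(out / "confusion_loocv.csv")
        res["territorial"].to_csv(out / "territorial.csv")
        model = res["model"]
        io.write_report(
            {
                "variables": model.variables,
                "eigenvalues": model.eigenvalues,
                "canonical_correlations": model.canonical_correlations,
                "wilks": model.wilks,
                "pillai": model.pillai,
                "standardized_coefficients": model.standardized_coefficients,
                "loadings": model.loadings,
                "centroids": model.centroids,
                "hit_ratio": res["classification"].hit_ratio,
                "loocv_hit_ratio": res["classification"].loocv_hit_ratio,
                "press_q": res["classification"].press_q,
            },
            out / "cda.json",
        )

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["checksums"][f.name] = _checksum(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest
    return artifacts
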