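"""End-to-end orchestration: DE -> crossover -> convergence -> report.

``run_all`` executes the full analysis graph on either files on disk or
one of the built-in presets, writes every intermediate artefact as TSV /
GMT / plain text, and serialises a JSON report with per-stage counts,
the convergence results, the Venn decomposition, a config echo, input
checksums and the package version.  All randomness flows from a single
top-level seed; stages draw derived sub-seeds so they rerun identically
in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from . import __version__
from .convergence import convergence_test, core_set, venn_decompose
from .crossover import (
    crossover_screen,
    read_target_table,
    significant_set,
    write_crossover_results,
)
from .de import DEConfig, apply_cutoffs, de_test, read_count_matrix, write_de_results
from .genesets import GeneSet, read_gmt, read_id_list, write_gmt, write_id_list
from .simulate import SimConfig, paper_fixture, simulate_counts, simulate_targets

__all__ = ["RunConfig", "run_all", "write_simulated_inputs", "load_config"]


@dataclass
class RunConfig:
    """Thresholds, engine choices and paths for a full pipeline run."""

    fc_threshold: float = 2.5
    alpha_de: float = 0.05
    alpha_crossover: float = 0.01
    alpha_convergence: float = 0.05
    test_engine: str = "nb_wald"
    universe_mode: str = "upregulated"  # or "all_expressed"
    seed: int = 17
    preset: str | None = None  # "paper-fixture" | "null" | "planted"
    counts: str | None = None
    samples: str | None = None
    lengths: str | None = None
    targets: str | None = None
    genesets: str | None = None  # GMT of disease gene lists
    rest: str | None = None      # one-column miRNA list
    background: str | None = None
    outdir: str = "mircross_out"

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_crossover", "alpha_convergence"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.fc_threshold <= 1.0:
            raise ValueError(f"fc_threshold must exceed 1, got {self.fc_threshold}")


def load_config(path: str | Path) -> RunConfig:
    """Flat key-value config file (YAML-compatible subset)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must be a flat key: value mapping")
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_simulated_inputs(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    """Materialise a preset's inputs as the standard file formats."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if cfg.preset == "paper-fixture":
        fx = paper_fixture()
        cm, targets, background = fx.counts, fx.targets, fx.background
        disease = list(fx.disease_genes.values())
        write_id_list(fx.rest_set, outdir / "rest11.txt")
        write_id_list(fx.upregulated, outdir / "up56.txt")
        paths["rest"] = outdir / "rest11.txt"
    elif cfg.preset in ("null", "planted"):
        sim = SimConfig(seed=cfg.seed) if cfg.preset == "planted" else SimConfig(
            seed=cfg.seed, planted_up=(), planted_crossover=(), enrichment_multiplier=1.0
        )
        cm = simulate_counts(sim)
        targets, disease_map, background = simulate_targets(sim)
        disease = list(disease_map.values())
    else:
        raise ValueError(f"unknown preset {cfg.preset!r}")

    cm.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="mirna_id")
    cm.condition.rename("condition").rename_axis("sample_id").reset_index().to_csv(
        outdir / "samples.tsv", sep="\t", index=False
    )
    cm.lengths.rename("length_nt").rename_axis("mirna_id").reset_index().to_csv(
        outdir / "lengths.tsv", sep="\t", index=False
    )
    targets.records.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    write_gmt(disease, outdir / "disease.gmt")
    write_id_list(background, outdir / "background.txt")
    paths.update(
        counts=outdir / "counts.tsv",
        samples=outdir / "samples.tsv",
        lengths=outdir / "lengths.tsv",
        targets=outdir / "targets.tsv",
        genesets=outdir / "disease.gmt",
        background=outdir / "background.txt",
    )
    return paths


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the report dict.

    Stage errors propagate annotated with the stage name.  The report
    and all intermediate artefacts are written under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.preset:
        paths = write_simulated_inputs(cfg, outdir / "inputs")
        cfg = replace(
            cfg,
            **{k: str(v) for k, v in paths.items()},
        )

    inputs = {
        k: Path(getattr(cfg, k))
        for k in ("counts", "samples", "lengths", "targets", "genesets")
        if getattr(cfg, k)
    }
    report: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(cfg).items()},
        "input_checksums": {k: _sha256(p) for k, p in inputs.items()},
        "stages": {},
    }

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # annotate and abort
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- differential expression -------------------------------------
    cm = _stage("de")(lambda: read_count_matrix(cfg.counts, cfg.samples, cfg.lengths))
    de_cfg = DEConfig(
        test=cfg.test_engine, fc_threshold=cfg.fc_threshold, alpha=cfg.alpha_de
    )
    de_results = _stage("de")(lambda: de_test(cm, de_cfg))
    upregulated = apply_cutoffs(de_results, cfg.fc_threshold, cfg.alpha_de)
    write_de_results(de_results, outdir / "de.tsv")
    write_id_list(upregulated, outdir / "upregulated.txt")
    report["stages"]["de"] = {
        "n_mirnas_tested": int(len(de_results)),
        "n_upregulated": len(upregulated),
        "upregulated": list(upregulated),
    }
    print(f"STAGE de: in={len(de_results)} out={len(upregulated)}")

    if len(upregulated) == 0:
        # nothing survived the filter: downstream enrichment is undefined
        report["stages"]["crossover"] = {}
        report["stages"]["convergence"] = {"results": [], "venn": None}
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report

    # --- crossover screen per disorder --------------------------------
    targets = _stage("crossover")(lambda: read_target_table(cfg.targets))
    disease_lists = _stage("crossover")(lambda: read_gmt(cfg.genesets))
    background = read_id_list(cfg.background, "background") if cfg.background else None
    disorder_sets: dict[str, GeneSet] = {}
    report["stages"]["crossover"] = {}
    for disease in disease_lists:
        res = _stage("crossover")(
            lambda d=disease: crossover_screen(
                upregulated, targets, d, background=background, alpha=cfg.alpha_crossover
            )
        )
        sig = significant_set(res, disease.name)
        disorder_sets[disease.name] = sig
        write_crossover_results(res, outdir / f"crossover_{disease.name.replace(':', '_')}.tsv")
        report["stages"]["crossover"][disease.name] = {
            "n_tested": len(res),
            "n_significant": len(sig),
            "significant": list(sig),
        }
        print(f"STAGE crossover[{disease.name}]: in={len(res)} out={len(sig)}")

    # --- convergence ---------------------------------------------------
    if cfg.rest:
        rest = read_id_list(cfg.rest, "REST_targeting")
        universe = (
            upregulated
            if cfg.universe_mode == "upregulated"
            else GeneSet.from_iterable("all_expressed", cm.counts.index)
        )
        rest_in = rest.intersect(universe, name=rest.name)
        conv_rows = []
        for name, dset in disorder_sets.items():
            conv = convergence_test(universe, dset, rest_in, alpha=cfg.alpha_convergence)
            conv_rows.append(asdict(conv))
            print(f"STAGE converge[{name}]: p={conv.p_value:.4g} significant={conv.significant}")
        venn_summary: dict | None = None
        names = list(disorder_sets)
        if len(names) == 3:
            venn = venn_decompose(
                disorder_sets[names[0]], disorder_sets[names[1]], disorder_sets[names[2]], rest_in
            )
            venn_summary = {
                "region_counts": venn.region_counts,
                "core": list(core_set(venn)),
            }
            print(f"STAGE venn: core={len(venn.core)}")
        report["stages"]["convergence"] = {"results": conv_rows, "venn": venn_summary}

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
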