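"""Synthetic inputs for every pipeline stage, plus a deterministic fixture.

Two kinds of artefact are produced:

* **Simulators** (:func:`simulate_counts`, :func:`simulate_targets`)
  draw miRNA count matrices and target tables with the statistical
  structure the analysis assumes — negative-binomial counts with planted
  upregulated miRNAs, and per-miRNA target sets that optionally
  oversample disease genes — all as pure functions of a seed.

* **A study fixture** (:func:`paper_fixture`) — a fully synthetic dataset
  constructed so that the whole chain (differential expression ->
  crossover screen -> convergence test) reproduces a specific published
  pattern of set cardinalities: 56 upregulated miRNAs, of which 43 are
  intellectual-disability(ID)-associated, 34 schizophrenia(SCZ)-associated
  and 15 autism(ASD)-associated; an 11-member REST-targeting subset
  overlapping those disorder sets in 11, 10 and 5 miRNAs respectively;
  and a 5-member three-disorder core.  Only the five core miRNA names
  are real identifiers; all other miRNAs carry synthetic ``mirSIM-``
  ids.  Every cardinality constraint is asserted at construction, and
  the packaged count matrix and target table are verified end-to-end
  through the real pipeline code so the fixture cannot silently drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .convergence import convergence_test, core_set, venn_decompose
from .crossover import TargetTable, crossover_screen, significant_set
from .de import CountMatrix, DEConfig, apply_cutoffs, de_test
from .genesets import GeneSet

__all__ = ["SimConfig", "simulate_counts", "simulate_targets", "PaperFixture", "paper_fixture"]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generators; every output is a pure function of ``seed``.

    Count model: per-miRNA baseline means are log-normal (median
    ``exp(base_mean_log_mean)`` normalised counts, clipped to
    [base_mean_min, base_mean_max]); counts are negative-binomial with
    dispersion ``nb_dispersion`` (variance mu + alpha mu^2); library
    sizes are log-normal around ``lib_size_mean`` total reads.  Planted
    miRNAs have their treated-condition mean multiplied by the given
    fold change; the default plants four miRNAs at measured
    fold-increases of 20.6, 7.95, 6.70 and 4.62.

    Target model: each miRNA draws a Poisson number of target genes from
    a universe of ``n_genes``; miRNAs listed in ``planted_crossover``
    sample genes of that disorder's disease list with selection weight
    ``enrichment_multiplier`` (1 = no enrichment).  Prediction scores
    are Uniform over ``score_bounds``; ``disease_score_shift`` adds a
    (clipped) bonus to scores of disease-listed targets.
    """

    n_mirnas: int = 200
    n_per_group: int = 3
    nb_dispersion: float = 0.05
    base_mean_log_mean: float = float(np.log(150.0))
    base_mean_log_sd: float = 1.0
    base_mean_min: float = 20.0
    base_mean_max: float = 5000.0
    lib_size_mean: float = 5e6
    lib_size_log_sd: float = 0.15
    length_range: tuple[int, int] = (20, 24)
    planted_up: tuple[tuple[int, float], ...] = (
        (0, 20.6),
        (1, 7.95),
        (2, 6.70),
        (3, 4.62),
    )
    n_genes: int = 2000
    targets_per_mirna_mean: float = 45.0
    score_bounds: tuple[float, float] = (50.0, 100.0)
    disease_sizes: tuple[tuple[str, int], ...] = (("DISEASE", 200),)
    enrichment_multiplier: float = 5.0
    planted_crossover: tuple[tuple[str, tuple[int, ...]], ...] = (
        ("DISEASE", tuple(range(20))),
    )
    disease_score_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_per_group, self.n_genes) <= 0:
            raise ValueError("all sizes must be > 0")
        for idx, fc in self.planted_up:
            if fc <= 1.0:
                raise ValueError(f"planted fold changes must exceed 1, got {fc} at index {idx}")
            if not (0 <= idx < self.n_mirnas):
                raise ValueError(f"planted index {idx} outside miRNA range")

    def mirna_ids(self) -> list[str]:
        return [f"mirSIM-{i:04d}" for i in range(self.n_mirnas)]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(cfg: SimConfig, mirna_ids: list[str] | None = None) -> CountMatrix:
    """Negative-binomial count matrix with planted upregulated miRNAs."""
    rng = np.random.default_rng(cfg.seed)
    ids = mirna_ids if mirna_ids is not None else cfg.mirna_ids()
    if len(ids) != cfg.n_mirnas:
        raise ValueError("mirna_ids length must equal cfg.n_mirnas")

    base = np.exp(rng.normal(cfg.base_mean_log_mean, cfg.base_mean_log_sd, cfg.n_mirnas))
    base = np.clip(base, cfg.base_mean_min, cfg.base_mean_max)
    fc = np.ones(cfg.n_mirnas)
    for idx, f in cfg.planted_up:
        fc[idx] = f

    n = cfg.n_per_group
    lib = np.exp(rng.normal(np.log(cfg.lib_size_mean), cfg.lib_size_log_sd, 2 * n))
    rel_depth = lib / cfg.lib_size_mean
    lengths = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, cfg.n_mirnas)

    cols, data = [], []
    for s in range(2 * n):
        treated = s >= n
        mu = base * (fc if treated else 1.0) * rel_depth[s]
        data.append(_nb_draw(rng, mu, cfg.nb_dispersion))
        cols.append(f"{'treated' if treated else 'control'}_{(s % n) + 1}")
    counts = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    condition = pd.Series(
        ["control"] * n + ["treated"] * n, index=cols, name="condition"
    )
    lengths_s = pd.Series(lengths, index=ids, name="length_nt")
    return CountMatrix(counts=counts, condition=condition, lengths=lengths_s)


def simulate_targets(
    cfg: SimConfig, mirna_ids: list[str] | None = None
) -> tuple[TargetTable, dict[str, GeneSet], GeneSet]:
    """Target table, disease gene lists, and the background universe.

    Disease lists are disjoint random blocks of the gene universe.
    Returns (targets, {disorder: gene set}, background).
    """
    rng = np.random.default_rng(cfg.seed + 1)  # decoupled from the count stream
    ids = mirna_ids if mirna_ids is not None else cfg.mirna_ids()
    genes = np.array([f"GENE{g:05d}" for g in range(1, cfg.n_genes + 1)])

    shuffled = rng.permutation(cfg.n_genes)
    disease_sets: dict[str, GeneSet] = {}
    disease_idx: dict[str, np.ndarray] = {}
    offset = 0
    for name, size in cfg.disease_sizes:
        take = shuffled[offset : offset + size]
        if len(take) < size:
            raise ValueError("disease lists exceed the gene universe")
        disease_idx[name] = take
        disease_sets[name] = GeneSet.from_iterable(name, genes[np.sort(take)])
        offset += size

    planted = {name: set(idxs) for name, idxs in cfg.planted_crossover}
    lo, hi = cfg.score_bounds
    rows = []
    for i, mid in enumerate(ids):
        n_t = max(5, int(rng.poisson(cfg.targets_per_mirna_mean)))
        n_t = min(n_t, cfg.n_genes)
        weights = np.ones(cfg.n_genes)
        for name, idx_set in planted.items():
            if i in idx_set:
                weights[disease_idx[name]] = cfg.enrichment_multiplier
        weights = weights / weights.sum()
        chosen = rng.choice(cfg.n_genes, size=n_t, replace=False, p=weights)
        scores = rng.uniform(lo, hi, n_t)
        if cfg.disease_score_shift:
            in_any = np.zeros(n_t, dtype=bool)
            for idx in disease_idx.values():
                in_any |= np.isin(chosen, idx)
            scores = np.where(
                in_any, np.clip(scores + cfg.disease_score_shift, lo, hi), scores
            )
        for g, s in zip(chosen, scores):
            rows.append((mid, genes[g], float(s)))

    table = TargetTable(
        records=pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score"]),
        score_bounds=cfg.score_bounds,
    )
    background = GeneSet.from_iterable("background", genes)
    return table, disease_sets, background


# ---------------------------------------------------------------------------
# study fixture
# ---------------------------------------------------------------------------

CORE_MIRNAS = ("miR-26a", "miR-26b", "miR-153", "miR-181a", "miR-548")

_FIXTURE_SEED = 104_801  # frozen: the fixture is a constant, not a simulation

# expected cardinalities, asserted at construction
_EXPECT = {
    "up": 56,
    "ID": 43,
    "SCZ": 34,
    "ASD": 15,
    "REST": 11,
    "REST&ID": 11,
    "REST&SCZ": 10,
    "REST&ASD": 5,
    "ASD&SCZ": 13,
    "core": 5,
}


@dataclass(frozen=True)
class PaperFixture:
    """Deterministic dataset reproducing the published set cardinalities."""

    upregulated: GeneSet
    disorder_sets: dict[str, GeneSet]
    rest_set: GeneSet
    core: GeneSet
    counts: CountMatrix
    targets: TargetTable
    disease_genes: dict[str, GeneSet]
    background: GeneSet
    all_mirnas: tuple[str, ...] = field(default=())


def _fixture_memberships() -> tuple[list[str], dict[str, list[str]], list[str]]:
    """56 miRNA ids with disorder/REST memberships satisfying all overlaps."""
    core = list(CORE_MIRNAS)
    synth = [f"mirSIM-{i:03d}" for i in range(6, 57)]  # 51 synthetic ids
    up = core + synth  # positions 0..55
    # membership layout by position:
    #   0-4   core: REST, ID, SCZ, ASD
    #   5-9   REST, ID, SCZ
    #   10    REST, ID
    #   11-18 ID, SCZ, ASD
    #   19-20 ID, ASD
    #   21-26 ID, SCZ
    #   27-42 ID only
    #   43-52 SCZ only
    #   53-55 none
    rest = up[0:11]
    id_set = up[0:43]
    scz = up[0:10] + up[11:19] + up[21:27] + up[43:53]
    asd = up[0:5] + up[11:21]
    return up, {"ID": id_set, "SCZ": scz, "ASD": asd}, rest


def _fixture_counts(up: list[str]) -> CountMatrix:
    # a large null background keeps the planted mass a modest share of the
    # library, so FPKM fold changes stay close to the planted values
    n_null = 944
    null_ids = [f"mirSIM-{i:03d}" for i in range(100, 100 + n_null)]
    ids = up + null_ids
    rng = np.random.default_rng(_FIXTURE_SEED)
    fcs = rng.uniform(6.0, 16.0, len(up))
    # low dispersion by design: fixture effects must sit decisively clear
    # of the 2.5-fold / adjusted-p thresholds so the designed sets are
    # recovered exactly, every time
    cfg = SimConfig(
        n_mirnas=len(ids),
        nb_dispersion=0.02,
        base_mean_min=50.0,
        planted_up=tuple((i, float(f)) for i, f in enumerate(fcs)),
        seed=_FIXTURE_SEED,
    )
    return simulate_counts(cfg, mirna_ids=ids)


def _fixture_targets(
    up: list[str], disorder_members: dict[str, list[str]]
) -> tuple[TargetTable, dict[str, GeneSet], GeneSet]:
    """Targets giving each member miRNA a decisive overlap with its disorders.

    Disease gene lists are disjoint 200-gene blocks of a 2000-gene
    universe; a member miRNA receives 15 genes from each of its
    disorders' lists plus neutral filler to 45 targets, so member
    overlaps are far beyond the 0.01 significance bound and non-member
    overlaps are exactly zero.
    """
    rng = np.random.default_rng(_FIXTURE_SEED + 7)
    genes = [f"GENE{g:05d}" for g in range(1, 2001)]
    blocks = {"ID": genes[0:200], "SCZ": genes[200:400], "ASD": genes[400:600]}
    filler = genes[600:]
    rows = []
    for mid in up:
        chosen: list[str] = []
        for disorder, members in disorder_members.items():
            if mid in members:
                chosen.extend(rng.choice(blocks[disorder], 15, replace=False))
        n_fill = 45 - len(chosen)
        chosen.extend(rng.choice(filler, n_fill, replace=False))
        scores = rng.uniform(50.0, 100.0, len(chosen))
        rows.extend((mid, g, float(s)) for g, s in zip(chosen, scores))
    table = TargetTable(records=pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score"]))
    disease = {d: GeneSet.from_iterable(d, b) for d, b in blocks.items()}
    background = GeneSet.from_iterable("background", genes)
    return table, disease, background


def _check_cardinalities(
    up: list[str], disorders: dict[str, list[str]], rest: list[str]
) -> None:
    rest_s = set(rest)
    got = {
        "up": len(up),
        "ID": len(disorders["ID"]),
        "SCZ": len(disorders["SCZ"]),
        "ASD": len(disorders["ASD"]),
        "REST": len(rest),
        "REST&ID": len(rest_s & set(disorders["ID"])),
        "REST&SCZ": len(rest_s & set(disorders["SCZ"])),
        "REST&ASD": len(rest_s & set(disorders["ASD"])),
        "ASD&SCZ": len(set(disorders["ASD"]) & set(disorders["SCZ"])),
        "core": len(set(disorders["ID"]) & set(disorders["SCZ"]) & set(disorders["ASD"]) & rest_s),
    }
    if got != _EXPECT:
        raise AssertionError(f"fixture cardinalities inconsistent: {got} != {_EXPECT}")
    if not set(disorders["ASD"]) <= set(disorders["ID"]):
        raise AssertionError("fixture requires ASD subset of ID")


def paper_fixture(verify: bool = True) -> PaperFixture:
    """Build the fixture; optionally verify it end-to-end.

    With ``verify=True`` (the default) the packaged count matrix and
    target table are pushed through the real differential-expression
    filter and crossover screen and the recovered sets are required to
    equal the designed memberships exactly; construction raises
    otherwise.
    """
    up, disorders, rest = _fixture_memberships()
    _check_cardinalities(up, disorders, rest)
    counts = _fixture_counts(up)
    targets, disease_genes, background = _fixture_targets(up, disorders)

    fixture = PaperFixture(
        upregulated=GeneSet.from_iterable("upregulated", up),
        disorder_sets={d: GeneSet.from_iterable(d, m) for d, m in disorders.items()},
        rest_set=GeneSet.from_iterable("REST_targeting", rest),
        core=GeneSet.from_iterable("core", CORE_MIRNAS),
        counts=counts,
        targets=targets,
        disease_genes=disease_genes,
        background=background,
        all_mirnas=tuple(counts.counts.index),
    )
    if verify:
        _verify_fixture(fixture)
    return fixture


def _verify_fixture(fx: PaperFixture) -> None:
    survivors = apply_cutoffs(de_test(fx.counts, DEConfig()))
    if set(survivors) != set(fx.upregulated):
        raise AssertionError("fixture DE stage does not recover the designed 56 miRNAs")
    for disorder, designed in fx.disorder_sets.items():
        res = crossover_screen(
            fx.upregulated, fx.targets, fx.disease_genes[disorder], background=fx.background
        )
        got = significant_set(res, disorder)
        if set(got) != set(designed):
            raise AssertionError(
                f"fixture crossover stage does not recover the designed {disorder} set"
            )
    venn = venn_decompose(
        fx.disorder_sets["ID"], fx.disorder_sets["SCZ"], fx.disorder_sets["ASD"], fx.rest_set
    )
    if set(core_set(venn)) != set(fx.core):
        raise AssertionError("fixture Venn core does not equal the designed core set")
    for disorder, expect_sig in (("ID", True), ("SCZ", True), ("ASD", False)):
        conv = convergence_test(fx.upregulated, fx.disorder_sets[disorder], fx.rest_set)
        if conv.significant != expect_sig:
            raise AssertionError(f"fixture convergence call for {disorder} unexpected")
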