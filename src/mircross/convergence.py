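"""Second-level convergence test and three-disorder Venn decomposition.

Given the set of upregulated miRNAs (the universe), the per-disorder
disease-associated miRNA sets, and the subset of miRNAs predicted to
target a gene of interest (here the REST/NRSF transcript), this module
asks: are the gene-targeting miRNAs over-represented among the
disorder-associated ones?  The test is a central hypergeometric upper
tail — draw ``|rest_set|`` miRNAs from the universe and count how many
land in the disorder set — with significance at p < 0.05 by default.

The Venn decomposition partitions a miRNA collection into the seven
regions of three named sets; the *core set* is the triple intersection,
which, computed over the REST-targeting collection, is the group of
miRNAs shared by all three disorders.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genesets import GeneSet
from .nchg import HypergeomParams, hypergeom_sf

__all__ = ["ConvergenceResult", "VennSummary", "convergence_test", "venn_decompose", "core_set"]


@dataclass(frozen=True)
class ConvergenceResult:
    disorder: str
    n_universe: int       # M: upregulated miRNAs
    n_disorder: int       # D: disorder-associated among them
    n_rest: int           # R: REST-targeting among them
    overlap: int          # x: disorder-associated AND REST-targeting
    p_value: float
    significant: bool


@dataclass(frozen=True)
class VennSummary:
    """Seven-region partition of a collection by three named sets.

    ``regions`` keys are frozensets of the set names a region belongs to
    (the empty frozenset is the outside region).  ``core`` lists the
    members of the triple intersection.
    """

    set_names: tuple[str, str, str]
    regions: dict[frozenset, tuple[str, ...]]
    core: tuple[str, ...]

    @property
    def region_counts(self) -> dict[str, int]:
        out = {}
        for key, members in self.regions.items():
            label = "&".join(sorted(key)) if key else "none"
            out[label] = len(members)
        return out


def _require_subset(sub: GeneSet, universe: GeneSet, what: str) -> None:
    extra = sorted(sub.as_set() - universe.as_set())
    if extra:
        raise ValueError(f"{what} contains ids outside the universe: {extra}")


def convergence_test(
    universe: GeneSet, disorder_set: GeneSet, rest_set: GeneSet, alpha: float = 0.05
) -> ConvergenceResult:
    """Hypergeometric enrichment of rest_set within disorder_set.

    p = P(X >= |overlap|) with X ~ Hypergeom(N=|universe|,
    K=|disorder_set|, n=|rest_set|).  Both sets must be subsets of the
    universe; offending identifiers are reported otherwise.
    """
    _require_subset(disorder_set, universe, f"disorder set {disorder_set.name!r}")
    _require_subset(rest_set, universe, f"REST-targeting set {rest_set.name!r}")
    overlap = len(disorder_set.as_set() & rest_set.as_set())
    params = HypergeomParams(
        N=len(universe), K=len(disorder_set), n=len(rest_set), k=overlap
    )
    p = hypergeom_sf(params)
    return ConvergenceResult(
        disorder=disorder_set.name,
        n_universe=params.N,
        n_disorder=params.K,
        n_rest=params.n,
        overlap=overlap,
        p_value=p,
        significant=p < alpha,
    )


def venn_decompose(
    set_a: GeneSet, set_b: GeneSet, set_c: GeneSet, collection: GeneSet
) -> VennSummary:
    """Exact 7-region partition of ``collection`` by three sets."""
    for s in (set_a, set_b, set_c):
        _require_subset(s.intersect(collection, name=s.name), collection, f"set {s.name!r}")
    names = (set_a.name, set_b.name, set_c.name)
    membership = {
        set_a.name: set_a.as_set(),
        set_b.name: set_b.as_set(),
        set_c.name: set_c.as_set(),
    }
    regions: dict[frozenset, list[str]] = {}
    for m in collection:
        key = frozenset(n for n in names if m in membership[n])
        regions.setdefault(key, []).append(m)
    full = frozenset(names)
    core = tuple(regions.get(full, []))
    return VennSummary(
        set_names=names,
        regions={k: tuple(v) for k, v in regions.items()},
        core=core,
    )


def core_set(venn: VennSummary, name: str = "core") -> GeneSet:
    """Triple-intersection members of a Venn summary, order-stable."""
    return GeneSet.from_iterable(name, venn.core)
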