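"""Grouping of species-specific metabolites into functional units.

Metabolites that belong to at least two overrepresented pathways and share
most of those pathways are merged into functional units — groups of
metabolites representing one biological theme.  Sharing is measured either
by Jaccard similarity of the pathway sets (default) or by the overlap
fraction relative to the smaller set; the merge threshold reads "more than
two-thirds".  Merging is agglomerative and deterministic: the most similar
pair merges first, ties break lexicographically, and a unit's pathway set
is the union of its members' sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class FunctionalUnit:
    unit_id: str
    metabolites: set[str]
    pathways: set[str]
    tissue: str = ""
    lineage: str = ""


def _similarity(a: set, b: set, mode: str) -> float:
    if not a or not b:
        return 0.0
    inter = len(a & b)
    if mode == "jaccard":
        return inter / len(a | b)
    if mode == "min-fraction":
        return inter / min(len(a), len(b))
    raise ValueError(f"unknown similarity mode {mode!r}")


def group_functional_units(
    metab_pathways: dict[str, set[str]],
    threshold: float = 2.0 / 3.0,
    similarity: str = "jaccard",
    tissue: str = "",
    lineage: str = "",
) -> list[FunctionalUnit]:
    """Incrementally merge metabolites sharing most overrepresented pathways.

    Only metabolites with >= 2 overrepresented pathways are eligible.  Units
    merge while some pair has similarity strictly greater than
    ``threshold``; the pair with the highest similarity merges first (ties
    by lexicographically smallest member id), and the merged unit carries
    the union of pathway sets.  Returns units sorted by smallest member id;
    singletons are returned as single-member units.
    """
    eligible = {m: set(ps) for m, ps in metab_pathways.items() if len(ps) >= 2}
    clusters: dict[str, tuple[set[str], set[str]]] = {
        m: ({m}, set(ps)) for m, ps in eligible.items()
    }

    def best_pair():
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                s = _similarity(clusters[a][1], clusters[b][1], similarity)
                if s > threshold and (best is None or s > best[0]):
                    best = (s, a, b)
        return best

    while True:
        pair = best_pair()
        if pair is None:
            break
        _, a, b = pair
        mets = clusters[a][0] | clusters[b][0]
        paths = clusters[a][1] | clusters[b][1]
        del clusters[a], clusters[b]
        clusters[min(mets)] = (mets, paths)

    units = []
    for i, key in enumerate(sorted(clusters)):
        mets, paths = clusters[key]
        units.append(FunctionalUnit(
            unit_id=f"U{i + 1:03d}", metabolites=mets, pathways=paths,
            tissue=tissue, lineage=lineage,
        ))
    return units
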