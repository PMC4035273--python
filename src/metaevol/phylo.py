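"""Lineage branch lengths for the four-species design.

The comparison involves humans, chimpanzees, rhesus macaques and mice.  Each
species contributes one terminal evolutionary lineage:

* ``human`` / ``chimp`` — the two branches since the human–chimpanzee split,
  ~6.5 million years (MY) each.
* ``macaque_anc`` — the branch connecting the human–chimpanzee ancestor with
  macaques.  With a human–macaque split at ~29.5 MY this branch is
  29.5 − 6.5 = 23 MY.
* ``mouse_anc`` — the branch connecting the primate ancestor with mice.
  With a rodent–primate split at ~130 MY this branch is 130 − 29.5 ≈ 101 MY
  (rounded; configurable).

Divergence proportions are regressed on these lengths, so only relative
magnitudes matter for fold-change comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Phylogeny:
    """Per-lineage branch lengths in million years (MY)."""

    lineage_lengths: dict[str, float] = field(
        default_factory=lambda: {
            "human": 6.5,
            "chimp": 6.5,
            "macaque_anc": 23.0,
            "mouse_anc": 101.0,
        }
    )

    def __post_init__(self) -> None:
        for name, length in self.lineage_lengths.items():
            if not length > 0:
                raise ValueError(f"branch length for {name!r} must be > 0, got {length}")

    def __getitem__(self, lineage: str) -> float:
        return self.lineage_lengths[lineage]


def make_phylogeny(
    human_my: float = 6.5,
    chimp_my: float = 6.5,
    macaque_my: float = 23.0,
    mouse_my: float = 101.0,
) -> Phylogeny:
    """Build a :class:`Phylogeny` from the four terminal-lineage lengths.

    Parameters are in million years.  All must be strictly positive.
    """
    lengths = {
        "human": float(human_my),
        "chimp": float(chimp_my),
        "macaque_anc": float(macaque_my),
        "mouse_anc": float(mouse_my),
    }
    for name, length in lengths.items():
        if not length > 0:
            raise ValueError(f"branch length for {name!r} must be > 0, got {length}")
    return Phylogeny(lengths)
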