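"""Readers and writers for the plain-text interchange formats.

Matrices (peak and expression tables) are tab-delimited with the feature id
in the first column and sample ids in the header.  Pathways are stored as
GMT (one pathway per line: id, description, members) with a companion GMT
for enzyme sets and a two-column TSV of direct enzyme-metabolite links.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import PathwayDB, PeakTable, check_sample_metadata


def write_matrix(df: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_peak_table(table: PeakTable, prefix) -> None:
    """Write ``<prefix>.intensities.tsv`` and ``<prefix>.peaks.tsv``."""
    prefix = Path(prefix)
    write_matrix(table.intensities, prefix.with_suffix(".intensities.tsv"), "peak_id")
    table.peak_meta.to_csv(prefix.with_suffix(".peaks.tsv"), sep="\t", index_label="peak_id")


def read_peak_table(prefix, log_scale: bool = False) -> PeakTable:
    prefix = Path(prefix)
    intens = read_matrix(prefix.with_suffix(".intensities.tsv"))
    meta = pd.read_csv(prefix.with_suffix(".peaks.tsv"), sep="\t", index_col=0)
    return PeakTable(intens, meta, log_scale=log_scale)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return check_sample_metadata(meta)


def write_gmt(sets: dict[str, set[str]], names: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(sets):
            desc = names.get(pid, pid)
            members = "\t".join(sorted(sets[pid]))
            fh.write(f"{pid}\t{desc}\t{members}\n")


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            pid, desc, members = parts[0], parts[1], parts[2:]
            sets[pid] = set(m for m in members if m)
            names[pid] = desc
    return sets, names


def write_pathway_db(db: PathwayDB, prefix) -> None:
    """Write ``<prefix>.metabolites.gmt``, ``.enzymes.gmt`` and ``.links.tsv``."""
    prefix = Path(prefix)
    write_gmt(db.metabolites, db.names, prefix.with_suffix(".metabolites.gmt"))
    write_gmt(db.enzymes, db.names, prefix.with_suffix(".enzymes.gmt"))
    links = pd.DataFrame(sorted(db.links), columns=["enzyme", "metabolite"])
    links.to_csv(prefix.with_suffix(".links.tsv"), sep="\t", index=False)


def read_pathway_db(prefix) -> PathwayDB:
    prefix = Path(prefix)
    mets, names = read_gmt(prefix.with_suffix(".metabolites.gmt"))
    enzymes, _ = read_gmt(prefix.with_suffix(".enzymes.gmt"))
    links_df = pd.read_csv(prefix.with_suffix(".links.tsv"), sep="\t")
    links = set(map(tuple, links_df[["enzyme", "metabolite"]].itertuples(index=False)))
    return PathwayDB(metabolites=mets, enzymes=enzymes, links=links, names=names)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
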