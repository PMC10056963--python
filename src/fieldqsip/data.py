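"""Dataset container and plain-text I/O for fractionated qSIP experiments.

On-disk layout (all TSV/Newick/JSON, suitable for version control):

* ``fractions.tsv`` — tube_id, treatment, block, isotope, fraction_idx
  (1-based), density_g_ml, total_16s_copies
* ``counts.tsv`` — taxon_id plus one column per fraction-sample, named
  ``<tube_id>.F<fraction_idx>``
* ``taxonomy.tsv`` — taxon_id, lineage (semicolon-delimited 7-rank
  SILVA-style string, ``d__...;p__...;...;s__...``)
* ``tree.nwk`` — Newick phylogeny whose tips are taxon ids
* ``truth.json`` — simulator ground truth (synthetic data only)
* ``manifest.json`` — seed, constants version, package version
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .constants import CONSTANTS_VERSION

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

FRACTION_COLUMNS = [
    "tube_id", "treatment", "block", "isotope",
    "fraction_idx", "density_g_ml", "total_16s_copies",
]


def lineage_to_ranks(lineage: str) -> dict:
    """Split a semicolon-delimited lineage string into the 7 canonical ranks."""
    parts = [p.strip() for p in lineage.split(";")]
    if len(parts) != len(RANKS):
        raise ValueError(f"expected {len(RANKS)} ranks, got {len(parts)}: {lineage!r}")
    return dict(zip(RANKS, parts))


def ranks_to_lineage(row) -> str:
    return ";".join(str(row[r]) for r in RANKS)


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV (taxon_id, lineage) -> DataFrame with one column per rank."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if "lineage" not in raw.columns:
        raise ValueError("taxonomy file needs a 'lineage' column")
    ranks = raw["lineage"].apply(lineage_to_ranks).apply(pd.Series)
    ranks.index = raw["taxon_id"]
    return ranks


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    lin = taxonomy.apply(ranks_to_lineage, axis=1)
    pd.DataFrame({"taxon_id": taxonomy.index, "lineage": lin.values}).to_csv(
        path, sep="\t", index=False
    )


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


@dataclass
class QsipDataset:
    """In-memory bundle of everything one qSIP analysis consumes."""

    fractions: pd.DataFrame
    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    tree: dendropy.Tree | None = None
    truth: dict | None = None
    config: dict | None = field(default=None, repr=False)

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def n_tubes(self) -> int:
        return self.fractions["tube_id"].nunique()

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fractions[FRACTION_COLUMNS].to_csv(outdir / "fractions.tsv",
                                                sep="\t", index=False)
        self.counts.rename_axis("taxon_id").to_csv(outdir / "counts.tsv", sep="\t")
        if self.taxonomy is not None:
            write_taxonomy(self.taxonomy, outdir / "taxonomy.tsv")
        if self.tree is not None:
            self.tree.write(path=str(outdir / "tree.nwk"), schema="newick",
                            suppress_rooting=True, unquoted_underscores=True)
        if self.truth is not None:
            (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1,
                                                          sort_keys=True))
        manifest = {
            "constants_version": CONSTANTS_VERSION,
            "n_tubes": int(self.n_tubes),
            "n_taxa": int(len(self.taxa)),
            "config": self.config,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         sort_keys=True))
        return outdir

    @classmethod
    def read(cls, indir) -> "QsipDataset":
        indir = Path(indir)
        fractions = pd.read_csv(indir / "fractions.tsv", sep="\t")
        counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col="taxon_id")
        taxonomy = tree = truth = config = None
        if (indir / "taxonomy.tsv").exists():
            taxonomy = read_taxonomy(indir / "taxonomy.tsv")
        if (indir / "tree.nwk").exists():
            tree = read_tree(indir / "tree.nwk")
        if (indir / "truth.json").exists():
            truth = json.loads((indir / "truth.json").read_text())
        if (indir / "manifest.json").exists():
            config = json.loads((indir / "manifest.json").read_text()).get("config")
        return cls(fractions=fractions, counts=counts, taxonomy=taxonomy,
                   tree=tree, truth=truth, config=config)
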