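"""Readers, writers and validated containers for codon alignments, trees and variant tables.

The unit of analysis is an in-frame nucleotide CDS alignment with a designated
query (reference) species, paired with a phylogeny whose branch lengths are in
units of expected synonymous substitutions per codon site (dS).  Variants are
amino acid substitutions addressed by 1-based codon position on the *ungapped*
query CDS; the alignment object maintains the map from that coordinate system
to alignment columns.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignmentFormatError",
    "DegenerateAlignmentError",
    "TreeFormatError",
    "VariantValidationError",
    "CodonAlignment",
    "Phylogeny",
    "VariantRecord",
    "ScoreTable",
    "read_codon_alignment",
    "write_codon_alignment",
    "filter_ambiguous_sequences",
    "read_tree",
    "read_variant_table",
    "write_variant_table",
    "write_predictions",
    "read_score_table",
]

#: characters permitted in a fully unambiguous aligned CDS
VALID_CHARS = frozenset("ACGT-")
#: the 20 standard single-letter amino acids
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: sentinel written for missing numeric values in TSV output
MISSING_TOKEN = "NA"


class AlignmentFormatError(ValueError):
    """Malformed alignment input (length, uniqueness, framing)."""


class DegenerateAlignmentError(ValueError):
    """An alignment too sparse for any likelihood computation."""


class TreeFormatError(ValueError):
    """Malformed Newick input (lengths, labels)."""


class VariantValidationError(ValueError):
    """A variant row violating the amino acid / coordinate contract."""


# ---------------------------------------------------------------------------
# CodonAlignment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CodonAlignment:
    """Species-by-codon matrix of in-frame CDS with a designated query species.

    ``sequences`` maps species id to an aligned nucleotide string; all strings
    share one length divisible by 3.  ``species_ids`` fixes iteration order.
    """

    species_ids: list[str]
    sequences: dict[str, str]
    query_id: str

    def __post_init__(self) -> None:
        if len(set(self.species_ids)) != len(self.species_ids):
            raise AlignmentFormatError("duplicate species identifiers")
        if set(self.species_ids) != set(self.sequences):
            raise AlignmentFormatError("species_ids and sequences disagree")
        if self.query_id not in self.sequences:
            raise KeyError(f"query species {self.query_id!r} not in alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentFormatError(f"alignment length {length} not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[self.query_id]) // 3

    def codon(self, species: str, column: int) -> str:
        """Codon string of ``species`` at 0-based codon ``column``."""
        return self.sequences[species][3 * column : 3 * column + 3]

    def column(self, column: int) -> dict[str, str]:
        """All species' codons at one 0-based codon column."""
        if not 0 <= column < self.n_codons:
            raise IndexError(f"codon column {column} out of range")
        return {sp: self.codon(sp, column) for sp in self.species_ids}

    @property
    def query_codon_columns(self) -> list[int]:
        """Alignment column index for each ungapped query codon, in CDS order.

        A query codon participates in the ungapped CDS coordinate system iff it
        contains no gap character; codons of unknown bases ('NNN') still occupy
        coordinates.
        """
        q = self.sequences[self.query_id]
        return [c for c in range(self.n_codons) if "-" not in q[3 * c : 3 * c + 3]]

    def resolve_codon_pos(self, codon_pos: int) -> int:
        """Map a 1-based ungapped-query codon position to an alignment column."""
        columns = self.query_codon_columns
        if not 1 <= codon_pos <= len(columns):
            raise IndexError(
                f"codon position {codon_pos} outside query CDS (1..{len(columns)})"
            )
        return columns[codon_pos - 1]

    def replace_sequence(self, species: str, sequence: str) -> "CodonAlignment":
        new = dict(self.sequences)
        new[species] = sequence
        return CodonAlignment(list(self.species_ids), new, self.query_id)


def read_codon_alignment(path: str | Path, query_id: str) -> CodonAlignment:
    """Read an aligned, in-frame nucleotide FASTA into a :class:`CodonAlignment`.

    Case is normalised to upper; gaps are preserved.  Ambiguous nucleotides are
    accepted here — discarding them is a separate, explicit step
    (:func:`filter_ambiguous_sequences`) applied before likelihood work.
    """
    ids: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise AlignmentFormatError(f"duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        if len(seq) % 3 != 0:
            raise AlignmentFormatError(
                f"record {rec.id!r} has length {len(seq)}, not divisible by 3"
            )
        ids.append(rec.id)
        seqs[rec.id] = seq
    if not ids:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    if query_id not in seqs:
        raise KeyError(f"query species {query_id!r} not among records")
    return CodonAlignment(ids, seqs, query_id)


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in aln.species_ids:
            fh.write(f">{sp}\n{aln.sequences[sp]}\n")


def filter_ambiguous_sequences(aln: CodonAlignment) -> CodonAlignment:
    """Drop homologs containing ambiguous nucleotides; mask them in the query.

    Non-query sequences with any character outside ``{A,C,G,T,-}`` are removed
    before likelihood computation.  The query is never removed — dropping it
    would leave variant coordinates and the Rn/An counts undefined — instead
    each query codon containing an ambiguous character is replaced by ``NNN``,
    which downstream code treats as missing data while the codon keeps its
    place in the ungapped-CDS coordinate map.
    """
    kept: list[str] = []
    seqs: dict[str, str] = {}
    for sp in aln.species_ids:
        seq = aln.sequences[sp]
        if sp == aln.query_id:
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            masked = [
                c if set(c) <= VALID_CHARS else "NNN"
                for c in codons
            ]
            kept.append(sp)
            seqs[sp] = "".join(masked)
        elif set(seq) <= VALID_CHARS:
            kept.append(sp)
            seqs[sp] = seq
    if len(kept) == 1:  # query only
        raise DegenerateAlignmentError(
            "every homolog contains ambiguous nucleotides; no data left for the LRT"
        )
    return CodonAlignment(kept, seqs, aln.query_id)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class Phylogeny:
    """A tree over alignment species with branch lengths in dS units.

    Stored as parent/length arrays over nodes in postorder (root last), which
    is the order the pruning recursion consumes.  Polytomies are permitted.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.lengths) == len(self.labels) == n):
            raise ValueError("parent/lengths/labels size mismatch")
        if self.parent[-1] != -1:
            raise ValueError("root must be the last node in postorder")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n - 1):
            if self.parent[i] <= i:
                raise ValueError("nodes must be in postorder (children before parents)")
            self.children[self.parent[i]].append(i)
        self.tip_indices = [i for i in range(n) if not self.children[i]]
        tips = [self.labels[i] for i in self.tip_indices]
        if any(t is None for t in tips):
            raise TreeFormatError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            raise TreeFormatError("duplicate tip labels")
        if np.any(self.lengths[:-1] < 0) or np.any(~np.isfinite(self.lengths[:-1])):
            raise TreeFormatError("branch lengths must be finite and nonnegative")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        for nd in nodes:
            if nd.parent_node is None:
                parent.append(-1)
                lengths.append(0.0)
            else:
                parent.append(index[id(nd.parent_node)])
                if nd.edge.length is None:
                    raise TreeFormatError("missing branch length")
                lengths.append(float(nd.edge.length))
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise TreeFormatError("unlabelled tip")
                labels.append(nd.taxon.label.replace(" ", "_"))
            else:
                labels.append(None)
        return cls(parent, lengths, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree)

    # -- basic queries -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def total_length(self) -> float:
        """Tree length in dS units (sum over all non-root edges)."""
        return float(np.sum(self.lengths[:-1]))

    # -- transforms ----------------------------------------------------------

    def with_lengths(self, lengths: Sequence[float]) -> "Phylogeny":
        """Copy with new edge lengths (aligned to node index; root entry ignored)."""
        new = np.asarray(lengths, dtype=float).copy()
        if new.shape != self.lengths.shape:
            raise ValueError("length vector shape mismatch")
        new[-1] = 0.0
        return Phylogeny(self.parent.copy(), new, list(self.labels))

    def scaled(self, factor: float) -> "Phylogeny":
        return self.with_lengths(self.lengths * factor)

    def to_newick(self, support: Mapping[frozenset, float] | None = None) -> str:
        """Serialise to Newick; optional per-clade support becomes internal labels."""

        def clade(i: int) -> frozenset:
            if not self.children[i]:
                return frozenset([self.labels[i]])
            return frozenset().union(*(clade(c) for c in self.children[i]))

        def render(i: int) -> str:
            if not self.children[i]:
                body = self.labels[i]
            else:
                inner = ",".join(render(c) for c in self.children[i])
                label = ""
                if support is not None:
                    s = support.get(clade(i))
                    if s is not None:
                        label = f"{s:.3f}"
                body = f"({inner}){label}"
            if i == self.root:
                return body
            return f"{body}:{self.lengths[i]:.10g}"

        return render(self.root) + ";"

    def prune_tip(self, label: str) -> "Phylogeny":
        """Remove one tip (and any resulting unifurcation, merging its edges)."""
        if label not in self.tip_labels:
            raise KeyError(f"tip {label!r} not in tree")
        tree = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        taxa = [t for t in tree.taxon_namespace if t.label == label]
        tree.prune_taxa(taxa, suppress_unifurcations=True)
        return Phylogeny.from_dendropy(tree)

    def check_against_alignment(self, aln: CodonAlignment) -> None:
        """Fail fast when tree tips are not a subset of alignment species."""
        missing = set(self.tip_labels) - set(aln.species_ids)
        if missing:
            raise TreeFormatError(
                f"tree tips absent from alignment: {sorted(missing)}"
            )


def read_tree(path: str | Path) -> Phylogeny:
    """Read a Newick tree with branch lengths (dS units).

    Polytomies are permitted; negative or missing branch lengths and duplicate
    tip labels are format errors.
    """
    text = Path(path).read_text()
    try:
        return Phylogeny.from_newick(text)
    except dendropy.utility.error.DataParseError as exc:  # pragma: no cover
        raise TreeFormatError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One amino acid substitution addressed on the query's ungapped CDS."""

    gene_id: str
    codon_pos: int  # 1-based codon index on the ungapped query CDS
    ref_aa: str
    alt_aa: str
    label: str | None = None  # "positive" (phenotype-altering) | "negative"
    minor_allele_count: int | None = None
    category_tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.ref_aa not in AMINO_ACIDS or self.alt_aa not in AMINO_ACIDS:
            raise VariantValidationError(
                f"non-standard amino acid in {self.ref_aa}->{self.alt_aa}"
            )
        if self.ref_aa == self.alt_aa:
            raise VariantValidationError("ref_aa equals alt_aa")
        if self.codon_pos < 1:
            raise VariantValidationError("codon_pos must be >= 1")
        if self.label is not None and self.label not in {"positive", "negative"}:
            raise VariantValidationError(f"unknown label {self.label!r}")
        if self.minor_allele_count is not None and self.minor_allele_count < 0:
            raise VariantValidationError("minor_allele_count must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene_id, self.codon_pos, self.ref_aa, self.alt_aa)


_VARIANT_COLUMNS = ["gene", "codon_pos", "ref_aa", "alt_aa", "label", "mac", "tags"]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a TSV of variants (columns: gene, codon_pos, ref_aa, alt_aa;
    optional label, mac, tags)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "codon_pos", "ref_aa", "alt_aa"}
    if not required <= set(df.columns):
        raise AlignmentFormatError(
            f"variant table missing columns {sorted(required - set(df.columns))}"
        )
    records = []
    for _, row in df.iterrows():
        try:
            pos = int(row["codon_pos"])
        except ValueError as exc:
            raise AlignmentFormatError(
                f"non-integer codon_pos {row['codon_pos']!r}"
            ) from exc
        label = row.get("label") or None
        mac = row.get("mac")
        mac = int(mac) if mac not in (None, "", MISSING_TOKEN) else None
        tags = row.get("tags")
        tags = frozenset(t for t in (tags or "").split(",") if t)
        records.append(
            VariantRecord(
                gene_id=row["gene"],
                codon_pos=pos,
                ref_aa=row["ref_aa"],
                alt_aa=row["alt_aa"],
                label=label,
                minor_allele_count=mac,
                category_tags=tags,
            )
        )
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.gene_id,
                "codon_pos": r.codon_pos,
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "label": r.label or "",
                "mac": r.minor_allele_count if r.minor_allele_count is not None else "",
                "tags": ",".join(sorted(r.category_tags)),
            }
        )
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_predictions(rows: Iterable[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write per-variant prediction rows (p-values, Rn, An, constraint,
    probabilities, flags) as TSV with 'NA' for missing values."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

KEY_COLUMNS = ["gene", "codon_pos", "ref_aa", "alt_aa"]


class ScoreTable:
    """Per-variant scores from several prediction approaches.

    One row per variant key (gene, codon_pos, ref_aa, alt_aa); one numeric
    column per approach.  Missing scores are NaN in memory and 'NA' on disk —
    they are never silently imputed; downstream operations each declare their
    missing-data policy.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        if not set(KEY_COLUMNS) <= set(frame.columns):
            raise AlignmentFormatError(
                f"score table requires key columns {KEY_COLUMNS}"
            )
        if frame.columns.duplicated().any():
            raise AlignmentFormatError("duplicate approach column names")
        if frame.duplicated(subset=KEY_COLUMNS).any():
            raise AlignmentFormatError("duplicate variant keys in score table")
        self.frame = frame.reset_index(drop=True)

    @property
    def approaches(self) -> list[str]:
        return [c for c in self.frame.columns if c not in KEY_COLUMNS]

    def scores(self, approach: str) -> np.ndarray:
        return self.frame[approach].to_numpy(dtype=float)

    def matrix(self, approaches: Sequence[str] | None = None) -> np.ndarray:
        cols = list(approaches) if approaches is not None else self.approaches
        return self.frame[cols].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)

    def __len__(self) -> int:
        return len(self.frame)


def read_score_table(path: str | Path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN])
    return ScoreTable(df)
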