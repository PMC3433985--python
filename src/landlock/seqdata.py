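"""Aligned mtDNA sequence tables: reading, concatenation, haplotypes, variable sites.

The analyses downstream (distances, AMOVA, parsimony network) all start from an
alignment of mitochondrial sequences keyed by individual, with population,
species and sex metadata.  This module holds that container and the handful of
operations that turn raw region alignments into analysis-ready haplotypes:

* :func:`read_alignment` — FASTA + metadata CSV into a :class:`SequenceTable`;
* :func:`concatenate_regions` — join two region alignments (e.g. partial ND5
  and full cytochrome *b*) per individual;
* :func:`collapse_haplotypes` — identical sequences share a haplotype;
* :func:`variable_site_stats` / :func:`compare_variable_rates` — per-region
  variability and a Fisher exact comparison between regions.

Nucleotides are handled case-insensitively and ``U`` is treated as ``T``.
Sites carrying a gap or ambiguity code in any sequence are removed
alignment-wide ("complete deletion") before haplotype collapse, so haplotype
identity is unambiguous; variable-site statistics instead judge each site on
its unambiguous states and report the proportion over the full alignment
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = _CODE[ord("u")] = _CODE[ord("T")]

META_COLUMNS = ("individual_id", "population", "species", "sex")


class AlignmentError(ValueError):
    """Raised when sequences in a table are not a valid alignment."""


class MetadataError(KeyError):
    """Raised when FASTA ids cannot be resolved in the metadata table."""


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, other=255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGT?"[min(c, 4)] for c in codes)


@dataclass
class SequenceTable:
    """An alignment of sequences with per-individual metadata.

    Parameters
    ----------
    meta : pandas.DataFrame
        One row per individual, columns ``individual_id``, ``population``,
        ``species`` and optionally ``sex``; ids must be unique.
    sequences : list of str
        Aligned sequences, same order as ``meta`` rows, all equal length.
    region_name : str
        Label for the sequenced region (e.g. ``"ND5"``, ``"cytb"``,
        ``"ND5+cytb"``).
    """

    meta: pd.DataFrame
    sequences: list[str] = field(repr=False)
    region_name: str = "region"

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        if "individual_id" not in self.meta.columns:
            raise MetadataError("metadata must contain an 'individual_id' column")
        ids = self.meta["individual_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise AlignmentError(f"duplicate individual ids: {dups}")
        if len(self.sequences) != len(self.meta):
            raise AlignmentError(
                f"{len(self.sequences)} sequences but {len(self.meta)} metadata rows"
            )
        if self.sequences:
            length = len(self.sequences[0])
            for ind, seq in zip(ids, self.sequences):
                if len(seq) != length:
                    raise AlignmentError(
                        f"sequence for {ind!r} has length {len(seq)}, expected {length}"
                    )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return list(self.meta["individual_id"])

    def to_matrix(self) -> np.ndarray:
        """Return the alignment as an (n, L) uint8 code matrix."""
        if not self.sequences:
            return np.empty((0, 0), dtype=np.uint8)
        return np.stack([encode(s) for s in self.sequences])

    def subset(self, mask) -> "SequenceTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SequenceTable(
            meta=self.meta.iloc[idx].reset_index(drop=True),
            sequences=[self.sequences[i] for i in idx],
            region_name=self.region_name,
        )

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=str(ind), description="")
            for ind, seq in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class HaplotypeSet:
    """Unique sequences with individual membership and per-population counts.

    ``haplotypes`` maps haplotype id to its (complete-deletion) sequence;
    ``membership`` maps individual id to haplotype id; ``frequencies`` is a
    haplotype x population count table.
    """

    haplotypes: dict[str, str]
    membership: dict[str, str]
    frequencies: pd.DataFrame
    meta: pd.DataFrame

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def ids(self) -> list[str]:
        return list(self.haplotypes)

    def sequences(self) -> list[str]:
        return list(self.haplotypes.values())

    def to_frame(self) -> pd.DataFrame:
        """Haplotype table as a DataFrame (haplotype_id, sequence, per-pop counts)."""
        out = pd.DataFrame(
            {"haplotype_id": self.ids, "sequence": self.sequences()}
        ).set_index("haplotype_id")
        return out.join(self.frequencies)


def read_alignment(fasta_path, metadata_path, region_name: str = "region") -> SequenceTable:
    """Read a FASTA alignment plus metadata CSV into a :class:`SequenceTable`.

    The metadata CSV must have columns ``individual_id, population, species``
    (``sex`` optional).  Every FASTA id must resolve to a metadata row;
    metadata rows without a sequence are dropped with no error (the table is
    keyed by the alignment).

    Raises
    ------
    MetadataError
        If any FASTA id is missing from the metadata (all offenders listed).
    AlignmentError
        If sequence lengths differ (the offending id is named).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    meta = pd.read_csv(metadata_path, dtype=str)
    missing = [r.id for r in records if r.id not in set(meta["individual_id"])]
    if missing:
        raise MetadataError(f"ids absent from metadata: {missing}")
    meta = meta.set_index("individual_id", drop=False)
    rows = meta.loc[[r.id for r in records]].reset_index(drop=True)
    return SequenceTable(
        meta=rows,
        sequences=[str(r.seq).upper().replace("U", "T") for r in records],
        region_name=region_name,
    )


def concatenate_regions(first: SequenceTable, second: SequenceTable) -> SequenceTable:
    """Concatenate two region alignments individual-by-individual.

    Both tables must cover exactly the same individuals; metadata are taken
    from ``first``.  The result's length is the sum of the two region lengths.
    """
    ids_a, ids_b = set(first.ids), set(second.ids)
    if ids_a != ids_b:
        only_a = sorted(ids_a - ids_b)
        only_b = sorted(ids_b - ids_a)
        raise MetadataError(
            f"individuals present in one region only: {only_a + only_b}"
        )
    pos_b = {ind: i for i, ind in enumerate(second.ids)}
    seqs = [
        seq_a + second.sequences[pos_b[ind]]
        for ind, seq_a in zip(first.ids, first.sequences)
    ]
    return SequenceTable(
        meta=first.meta.copy(),
        sequences=seqs,
        region_name=f"{first.region_name}+{second.region_name}",
    )


def complete_deletion_mask(matrix: np.ndarray) -> np.ndarray:
    """Boolean mask of sites where every sequence has an unambiguous base."""
    return (matrix < 4).all(axis=0)


def collapse_haplotypes(table: SequenceTable) -> HaplotypeSet:
    """Collapse identical sequences into haplotypes.

    Sites with a gap or ambiguity in any individual are removed alignment-wide
    first, then identical remaining sequences share a haplotype.  Haplotypes
    are numbered ``H01, H02, ...`` in order of first occurrence, which makes
    the labelling deterministic for a given input order.
    """
    matrix = table.to_matrix()
    if matrix.size:
        matrix = matrix[:, complete_deletion_mask(matrix)]
    hap_of_seq: dict[bytes, str] = {}
    haplotypes: dict[str, str] = {}
    membership: dict[str, str] = {}
    for ind, row in zip(table.ids, matrix):
        key = row.tobytes()
        hap = hap_of_seq.get(key)
        if hap is None:
            hap = f"H{len(hap_of_seq) + 1:02d}"
            hap_of_seq[key] = hap
            haplotypes[hap] = decode(row)
        membership[ind] = hap
    counts = pd.crosstab(
        table.meta["individual_id"].map(membership),
        table.meta["population"],
    )
    counts = counts.reindex(index=list(haplotypes), fill_value=0)
    counts.index.name = "haplotype_id"
    counts.columns.name = "population"
    return HaplotypeSet(
        haplotypes=haplotypes,
        membership=membership,
        frequencies=counts,
        meta=table.meta.copy(),
    )


def variable_site_stats(table: SequenceTable) -> tuple[int, int, float]:
    """Count variable sites: (n_variable, n_sites, proportion).

    A site is variable iff at least two distinct unambiguous states are
    observed there.  The proportion uses the full alignment length as
    denominator; round only for display.
    """
    if len(table) < 2:
        raise AlignmentError("variable-site statistics need at least 2 sequences")
    matrix = table.to_matrix()
    n_sites = matrix.shape[1]
    n_variable = 0
    for j in range(n_sites):
        states = np.unique(matrix[:, j])
        if (states < 4).sum() >= 2:
            n_variable += 1
    return n_variable, n_sites, n_variable / n_sites


def compare_variable_rates(
    stats_a: tuple[int, int, float], stats_b: tuple[int, int, float]
) -> float:
    """Two-sided Fisher exact p for equal variability of two regions.

    The 2x2 table is (variable, invariant) x (region A, region B).
    """
    from scipy.stats import fisher_exact

    (va, na, _), (vb, nb, _) = stats_a, stats_b
    if na == 0 or nb == 0:
        raise AlignmentError("zero-length region")
    _, p = fisher_exact([[va, na - va], [vb, nb - vb]], alternative="two-sided")
    return float(p)
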