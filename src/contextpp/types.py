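"""Core domain containers for canonical miRNA targeting.

Coordinates are 0-based, half-open everywhere inside the package; the I/O
layer converts to 1-based inclusive at the user-facing boundary (the
convention of published site tables).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RNA_ALPHABET = frozenset("ACGUN")

SITE_8MER = "8mer"
SITE_7M8 = "7mer-m8"
SITE_7A1 = "7mer-A1"
SITE_6MER = "6mer"
SITE_OFF6 = "offset-6mer"

#: canonical site types scored by the model, strongest first
CANONICAL_SITE_TYPES = (SITE_8MER, SITE_7M8, SITE_7A1, SITE_6MER)
ALL_SITE_TYPES = CANONICAL_SITE_TYPES + (SITE_OFF6,)

SITE_TYPE_LENGTH = {
    SITE_8MER: 8,
    SITE_7M8: 7,
    SITE_7A1: 7,
    SITE_6MER: 6,
    SITE_OFF6: 6,
}

CONSERVATION_CLASSES = ("broadly_conserved", "mammalian_conserved", "poorly_conserved")


def validate_rna(seq: str, *, allow_n: bool = True, label: str = "sequence") -> str:
    """Return ``seq`` if it is a valid RNA string, else raise ValueError naming
    the offending position."""
    allowed = RNA_ALPHABET if allow_n else RNA_ALPHABET - {"N"}
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"non-nucleotide character {ch!r} at position {pos} in {label}"
            )
    return seq


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


_COMP = str.maketrans("ACGUN", "UGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """One representative ORF: 5'UTR / ORF / 3'UTR of an mRNA, keyed by its
    stop codon.  ``utr3`` is the longest annotated isoform."""

    transcript_id: str
    gene_id: str
    utr5: str
    orf: str
    utr3: str
    validate: bool = True

    def __post_init__(self) -> None:
        if self.validate:
            for name in ("utr5", "orf", "utr3"):
                validate_rna(getattr(self, name), label=f"{self.transcript_id}:{name}")
            if len(self.orf) % 3 != 0:
                raise ValueError(
                    f"{self.transcript_id}: ORF length {len(self.orf)} not divisible by 3"
                )
            if len(self.utr3) < 1:
                raise ValueError(f"{self.transcript_id}: empty 3' UTR")

    @property
    def stop_codon_end(self) -> int:
        """0-based offset of the first 3'-UTR nucleotide within the mRNA."""
        return len(self.utr5) + len(self.orf)

    @property
    def mrna(self) -> str:
        return self.utr5 + self.orf + self.utr3


@dataclass(frozen=True)
class MirnaFamily:
    """A seed family: all mature sRNAs sharing nucleotides 2-8."""

    family_id: str
    seed7: str
    members: tuple[str, ...]
    conservation_class: str = "poorly_conserved"

    def __post_init__(self) -> None:
        validate_rna(self.seed7, allow_n=False, label=f"{self.family_id}:seed7")
        if len(self.seed7) != 7:
            raise ValueError(f"{self.family_id}: seed must be 7 nt (miRNA nt 2-8)")
        if self.conservation_class not in CONSERVATION_CLASSES:
            raise ValueError(
                f"{self.family_id}: unknown conservation class {self.conservation_class!r}"
            )
        for m in self.members:
            if len(m) < 8:
                raise ValueError(
                    f"{self.family_id}: member {m!r} shorter than 8 nt"
                )
            if m[1:8] != self.seed7:
                raise ValueError(
                    f"{self.family_id}: member {m} nt 2-8 ({m[1:8]}) != seed {self.seed7}"
                )


@dataclass(frozen=True)
class Site:
    """A classified seed-match occurrence.  ``start``/``end`` are 0-based
    half-open offsets within the region (3' UTR or ORF)."""

    transcript_id: str
    family_id: str
    site_type: str
    start: int
    end: int
    region: str = "utr3"

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPE_LENGTH:
            raise ValueError(f"unknown site type {self.site_type!r}")
        expected = SITE_TYPE_LENGTH[self.site_type]
        if self.end - self.start != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, got "
                f"[{self.start},{self.end})"
            )
        if self.region not in ("utr3", "orf"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class ClusterSet:
    """3P-seq cleavage/polyadenylation clusters.

    Records carry the transcript, the 3'-UTR end position implied by the
    cluster (0-based offset from the stop codon, i.e. an isoform length),
    a tag count, and the dataset the tags come from.
    """

    records: pd.DataFrame  # columns: transcript_id, end_offset, tag_count, dataset_id

    COLUMNS = ("transcript_id", "end_offset", "tag_count", "dataset_id")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"cluster table missing columns {sorted(missing)}")
        if (self.records["tag_count"] < 0).any():
            raise ValueError("negative tag count in cluster table")
        if (self.records["end_offset"] < 1).any():
            raise ValueError("cluster end offset before position 1")

    def for_transcript(self, transcript_id: str) -> pd.DataFrame:
        return self.records[self.records["transcript_id"] == transcript_id]

    @property
    def dataset_ids(self) -> list[str]:
        return sorted(self.records["dataset_id"].unique())


@dataclass
class FoldChangeCompendium:
    """Genes x experiments log2 fold-change matrix Z with the binary
    site-indicator mask T (1 iff the gene carries a canonical 7-8 nt 3'-UTR
    site to the sRNA perturbed in that experiment)."""

    Z: pd.DataFrame
    T: pd.DataFrame

    def __post_init__(self) -> None:
        if self.Z.shape != self.T.shape:
            raise ValueError(
                f"Z {self.Z.shape} and T {self.T.shape} shapes differ"
            )
        if not (self.Z.index.equals(self.T.index) and self.Z.columns.equals(self.T.columns)):
            raise ValueError("Z and T must share gene ids and experiment ids")
        tvals = self.T.to_numpy()
        if not np.isin(tvals[~pd.isna(tvals)], (0, 1)).all():
            raise ValueError("T must be binary")
        if self.Z.index.duplicated().any():
            dupes = self.Z.index[self.Z.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.Z.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.Z.columns)


@dataclass
class IsoformProfile:
    """Tandem 3'-UTR isoform abundance profile for one transcript.

    ``ends`` are ascending 0-based end offsets (isoform lengths) within the
    3' UTR; ``abundances`` are the matching relative molecule frequencies
    and sum to 1.  The last end equals the longest-annotation UTR length.
    """

    transcript_id: str
    ends: np.ndarray
    abundances: np.ndarray
    total_tags: float = 0.0

    def __post_init__(self) -> None:
        self.ends = np.asarray(self.ends, dtype=int)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.ends.shape != self.abundances.shape:
            raise ValueError("ends and abundances must align")
        if len(self.ends) == 0:
            raise ValueError("profile needs at least one isoform")
        if not np.all(np.diff(self.ends) > 0):
            raise ValueError("isoform ends must be strictly increasing")
        if (self.abundances < 0).any():
            raise ValueError("negative isoform abundance")
        total = float(self.abundances.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")

    @property
    def longest_end(self) -> int:
        return int(self.ends[-1])

    @property
    def dominant_fraction(self) -> float:
        return float(self.abundances.max())
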