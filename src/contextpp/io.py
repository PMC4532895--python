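"""Readers/writers for the external file formats.

Formats (all plain text):

* transcripts: FASTA of mRNA sequences + TSV annotation table
  ``transcript_id  gene_id  utr5_len  orf_len  utr3_len``
* miRNA families: TSV ``family_id  seed7  member_seq  conservation_class``
* 3P-seq clusters: BED-like TSV ``transcript_id  end_offset  tag_count  dataset_id``
  (end offsets 1-based inclusive on disk == isoform length, stored as-is)
* fold-change matrix / site mask: TSV with a header row of experiment ids
  and gene ids in the first column; empty cells are missing, not zero.

Internal coordinates are 0-based half-open; user-facing site tables are
written 1-based inclusive.
"""
from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    ClusterSet,
    FoldChangeCompendium,
    MirnaFamily,
    Site,
    TranscriptModel,
    dna_to_rna,
    validate_rna,
)

__all__ = [
    "read_transcripts",
    "write_transcripts",
    "read_mirna_families",
    "write_mirna_families",
    "read_clusters",
    "write_clusters",
    "read_fold_change_matrix",
    "write_fold_change_matrix",
    "read_sites",
    "write_sites",
]


def read_transcripts(fasta_path, annotation_tsv_path, *, validate: bool = True) -> dict[str, TranscriptModel]:
    """Load transcript models from a FASTA of mRNA sequences plus the
    annotation table giving the 5'UTR/ORF/3'UTR segment lengths.

    DNA input is converted T->U.  Raises on annotation rows without a FASTA
    record (and vice versa) and on out-of-range segment boundaries.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = dna_to_rna(str(rec.seq))
    ann = pd.read_csv(annotation_tsv_path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    required = {"transcript_id", "gene_id", "utr5_len", "orf_len", "utr3_len"}
    missing_cols = required - set(ann.columns)
    if missing_cols:
        raise ValueError(f"annotation table missing columns {sorted(missing_cols)}")
    if ann["transcript_id"].duplicated().any():
        dup = ann.loc[ann["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise ValueError(f"duplicate transcript ids in annotation: {dup}")

    out: dict[str, TranscriptModel] = {}
    for row in ann.itertuples(index=False):
        tid = row.transcript_id
        if tid not in seqs:
            raise ValueError(f"annotation references absent FASTA id {tid!r}")
        seq = seqs[tid]
        u5, orf, u3 = int(row.utr5_len), int(row.orf_len), int(row.utr3_len)
        if u5 < 0 or orf < 0 or u3 < 0 or u5 + orf + u3 != len(seq):
            raise ValueError(
                f"{tid}: segment lengths ({u5},{orf},{u3}) do not tile the "
                f"{len(seq)} nt sequence"
            )
        validate_rna(seq, label=tid)
        out[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=row.gene_id,
            utr5=seq[:u5],
            orf=seq[u5 : u5 + orf],
            utr3=seq[u5 + orf :],
            validate=validate,
        )
    orphans = set(seqs) - set(out)
    if orphans:
        raise ValueError(f"FASTA records without annotation rows: {sorted(orphans)}")
    return out


def write_transcripts(transcripts: Iterable[TranscriptModel], fasta_path, annotation_tsv_path) -> None:
    transcripts = list(transcripts)
    records = [
        SeqRecord(Seq(t.mrna), id=t.transcript_id, description="")
        for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    ann = pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "gene_id": [t.gene_id for t in transcripts],
            "utr5_len": [len(t.utr5) for t in transcripts],
            "orf_len": [len(t.orf) for t in transcripts],
            "utr3_len": [len(t.utr3) for t in transcripts],
        }
    )
    ann.to_csv(annotation_tsv_path, sep="\t", index=False)


def read_mirna_families(tsv_path) -> dict[str, MirnaFamily]:
    """Load seed families, grouping member rows by identical nt 2-8.

    A member whose nt 2-8 differ from the declared seed is rejected, as are
    two rows giving the same family id different seeds.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"family_id", "seed7", "member_seq", "conservation_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"family table missing columns {sorted(missing)}")
    grouped: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        member = dna_to_rna(row.member_seq)
        seed = dna_to_rna(row.seed7)
        if len(member) < 8:
            raise ValueError(f"{row.family_id}: member {member!r} shorter than 8 nt")
        if member[1:8] != seed:
            raise ValueError(
                f"{row.family_id}: member nt 2-8 ({member[1:8]}) conflicts with "
                f"declared seed {seed}"
            )
        entry = grouped.setdefault(
            row.family_id,
            {"seed7": seed, "members": [], "conservation_class": row.conservation_class},
        )
        if entry["seed7"] != seed:
            raise ValueError(f"{row.family_id}: conflicting seeds {entry['seed7']} vs {seed}")
        if entry["conservation_class"] != row.conservation_class:
            raise ValueError(f"{row.family_id}: conflicting conservation classes")
        if member not in entry["members"]:
            entry["members"].append(member)
    return {
        fid: MirnaFamily(
            family_id=fid,
            seed7=v["seed7"],
            members=tuple(v["members"]),
            conservation_class=v["conservation_class"],
        )
        for fid, v in grouped.items()
    }


def write_mirna_families(families: Iterable[MirnaFamily], tsv_path) -> None:
    rows = []
    for fam in families:
        for member in fam.members:
            rows.append(
                {
                    "family_id": fam.family_id,
                    "seed7": fam.seed7,
                    "member_seq": member,
                    "conservation_class": fam.conservation_class,
                }
            )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_clusters(tsv_path) -> ClusterSet:
    df = pd.read_csv(
        tsv_path,
        sep="\t",
        dtype={"transcript_id": str, "dataset_id": str},
    )
    return ClusterSet(records=df[list(ClusterSet.COLUMNS)].copy())


def write_clusters(clusters: ClusterSet, tsv_path) -> None:
    clusters.records.to_csv(tsv_path, sep="\t", index=False)


def read_fold_change_matrix(tsv_path, site_mask_tsv_path) -> FoldChangeCompendium:
    """Read the log2 fold-change matrix and the matching site mask.

    Empty cells in the matrix are missing values (NaN), never zero.  The two
    tables must share gene and experiment keys exactly.
    """
    Z = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if Z.index.duplicated().any():
        dup = Z.index[Z.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in fold-change matrix: {dup}")
    T = pd.read_csv(site_mask_tsv_path, sep="\t", index_col=0)
    if Z.shape != T.shape or not Z.index.equals(T.index) or not Z.columns.equals(T.columns):
        raise ValueError("fold-change matrix and site mask have mismatched shape/keys")
    return FoldChangeCompendium(Z=Z, T=T.astype(int))


def write_fold_change_matrix(comp: FoldChangeCompendium, tsv_path, site_mask_tsv_path) -> None:
    comp.Z.to_csv(tsv_path, sep="\t")
    comp.T.to_csv(site_mask_tsv_path, sep="\t")


def write_sites(sites: Iterable[Site], tsv_path) -> None:
    """Write a user-facing site table, 1-based inclusive coordinates."""
    rows = [
        {
            "transcript_id": s.transcript_id,
            "family_id": s.family_id,
            "site_type": s.site_type,
            "start_1based": s.start + 1,
            "end_1based": s.end,  # half-open end == inclusive 1-based end
            "region": s.region,
        }
        for s in sites
    ]
    pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "family_id",
            "site_type",
            "start_1based",
            "end_1based",
            "region",
        ],
    ).to_csv(tsv_path, sep="\t", index=False)


def read_sites(tsv_path) -> list[Site]:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"transcript_id": str, "family_id": str})
    return [
        Site(
            transcript_id=row.transcript_id,
            family_id=row.family_id,
            site_type=row.site_type,
            start=int(row.start_1based) - 1,
            end=int(row.end_1based),
            region=row.region,
        )
        for row in df.itertuples(index=False)
    ]
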