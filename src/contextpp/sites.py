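"""Canonical seed-match site discovery and classification.

Canonical site types, target strand 5'->3' (seed7 = miRNA nt 2-8):

* 8mer      — match to miRNA nt 2-8 plus an A opposite position 1
* 7mer-m8   — match to miRNA nt 2-8
* 7mer-A1   — match to miRNA nt 2-7 plus an A opposite position 1
* 6mer      — match to miRNA nt 2-7
* offset-6mer — match to miRNA nt 3-8

Every seed-match locus receives exactly one label via the hierarchy
8mer > 7mer-m8 > 7mer-A1 > 6mer; offset-6mers are reported only where no
stronger call covers the locus.  Overlapping distinct loci are resolved by
priority, ties going to the 5'-most locus.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .types import (
    ALL_SITE_TYPES,
    CANONICAL_SITE_TYPES,
    SITE_6MER,
    SITE_7A1,
    SITE_7M8,
    SITE_8MER,
    SITE_OFF6,
    MirnaFamily,
    Site,
    TranscriptModel,
    reverse_complement,
)

__all__ = [
    "SiteSignatures",
    "seed_signatures",
    "find_sites",
    "count_orf_sites",
    "target_site_census",
    "RIBOSOME_SHADOW_NT",
]

#: sites whose 5' end falls within this many nt of the stop codon sit in the
#: path of the ribosome and are excluded from scoring by default
RIBOSOME_SHADOW_NT = 15

_PRIORITY = {t: i for i, t in enumerate(ALL_SITE_TYPES)}


@dataclass(frozen=True)
class SiteSignatures:
    """Target-strand k-mer signatures for one seed family."""

    family_id: str
    site_8mer: str
    site_7mer_m8: str
    site_7mer_a1: str
    site_6mer: str
    site_offset_6mer: str

    def as_dict(self) -> dict[str, str]:
        return {
            SITE_8MER: self.site_8mer,
            SITE_7M8: self.site_7mer_m8,
            SITE_7A1: self.site_7mer_a1,
            SITE_6MER: self.site_6mer,
            SITE_OFF6: self.site_offset_6mer,
        }


def seed_signatures(family: MirnaFamily) -> SiteSignatures:
    """Derive the five site signatures from the family seed.

    The 7mer-m8 is the reverse complement of nt 2-8; the position-1 adenosine
    is appended on the target 3' side; the 6mer is the reverse complement of
    nt 2-7; the offset-6mer of nt 3-8.
    """
    seed = family.seed7
    if "N" in seed:
        raise ValueError(f"{family.family_id}: seed contains N")
    m7m8 = reverse_complement(seed)  # matches miRNA nt 2-8
    mer6 = reverse_complement(seed[:6])  # nt 2-7
    off6 = reverse_complement(seed[1:7])  # nt 3-8
    return SiteSignatures(
        family_id=family.family_id,
        site_8mer=m7m8 + "A",
        site_7mer_m8=m7m8,
        site_7mer_a1=mer6 + "A",
        site_6mer=mer6,
        site_offset_6mer=off6,
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) match offsets, excluding windows with N."""
    hits = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i == -1:
            return hits
        hits.append(i)
        start = i + 1


def _classify_core_matches(seq: str, sig: SiteSignatures) -> list[tuple[str, int, int]]:
    """Classify every 6mer-core seed match in ``seq`` into exactly one
    canonical type, returning (site_type, start, end) tuples."""
    calls = []
    m8_char = sig.site_7mer_m8[0]
    for p in _find_all(seq, sig.site_6mer):
        has_m8 = p >= 1 and seq[p - 1] == m8_char
        has_a1 = p + 6 < len(seq) and seq[p + 6] == "A"
        if has_m8 and has_a1:
            calls.append((SITE_8MER, p - 1, p + 7))
        elif has_m8:
            calls.append((SITE_7M8, p - 1, p + 6))
        elif has_a1:
            calls.append((SITE_7A1, p, p + 7))
        else:
            calls.append((SITE_6MER, p, p + 6))
    return calls


def _resolve_overlaps(calls: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Greedy resolution of overlapping distinct loci: higher priority wins;
    on equal priority the 5'-most locus wins."""
    ordered = sorted(calls, key=lambda c: (_PRIORITY[c[0]], c[1]))
    kept: list[tuple[str, int, int]] = []
    for call in ordered:
        _, s, e = call
        if all(e <= ks or s >= ke for _, ks, ke in kept):
            kept.append(call)
    kept.sort(key=lambda c: c[1])
    return kept


def find_sites(
    utr3: str,
    family: MirnaFamily,
    *,
    transcript_id: str = "",
    region: str = "utr3",
    include_offset_6mer: bool = True,
    exclude_ribosome_shadow: bool = False,
) -> list[Site]:
    """Locate and classify all canonical seed-matched sites in a sequence.

    With ``exclude_ribosome_shadow`` sites overlapping the first 15 nt of the
    3' UTR are dropped (they sit in the path of the ribosome).
    """
    if not utr3:
        return []
    sig = seed_signatures(family)
    calls = _classify_core_matches(utr3, sig)
    if include_offset_6mer:
        covered = [(s, e) for _, s, e in calls]
        for p in _find_all(utr3, sig.site_offset_6mer):
            # suppressed wherever a stronger call covers any part of the locus
            if all(p + 6 <= s or p >= e for s, e in covered):
                calls.append((SITE_OFF6, p, p + 6))
    calls = _resolve_overlaps(calls)
    sites = [
        Site(
            transcript_id=transcript_id,
            family_id=family.family_id,
            site_type=t,
            start=s,
            end=e,
            region=region,
        )
        for t, s, e in calls
    ]
    if exclude_ribosome_shadow and region == "utr3":
        sites = [s for s in sites if s.start >= RIBOSOME_SHADOW_NT]
    return sites


def count_orf_sites(orf: str, family: MirnaFamily) -> dict[str, int]:
    """Occurrence counts of each canonical site type in an ORF, with the same
    one-label-per-locus hierarchy and overlap resolution as ``find_sites``."""
    counts = {t: 0 for t in ALL_SITE_TYPES}
    for site in find_sites(orf, family, region="orf"):
        counts[site.site_type] += 1
    return counts


def target_site_census(
    transcripts: Iterable[TranscriptModel] | Mapping[str, TranscriptModel],
    family: MirnaFamily,
) -> int:
    """Transcriptome-wide 3'-UTR seed-match count for a family (the raw TA
    count): occurrences of the 6mer core (match to miRNA nt 2-7) at distinct
    offsets over all annotated 3' UTRs, which subsumes 7-8mer loci."""
    if isinstance(transcripts, Mapping):
        transcripts = transcripts.values()
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("empty transcriptome")
    core = seed_signatures(family).site_6mer
    return sum(len(_find_all(t.utr3, core)) for t in transcripts)
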