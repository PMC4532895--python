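"""The 14 per-site features of the context++ efficacy model and their
trimmed scaling.

Continuous features are affinely rescaled by the 5th/95th percentiles of
their training distribution per site type ("trimmed normalization": values
are *not* clipped, so scaled values can fall outside [0, 1]).  Count
features (Off6m, ORF8m) and the nucleotide-identity categories (sRNA1,
sRNA8, site8 — encoded downstream as A/C/G indicators against a U
reference) pass through unscaled.

The packaged scaling table carries the published percentiles; a table for a
new training set is produced by :func:`contextpp.training.fit_scaling`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .accessibility import PartitionFunctionProvider
from .profiles import air, weighted_feature
from .sites import count_orf_sites, find_sites, seed_signatures
from .types import (
    SITE_6MER,
    SITE_7A1,
    SITE_7M8,
    SITE_8MER,
    SITE_OFF6,
    CANONICAL_SITE_TYPES,
    IsoformProfile,
    MirnaFamily,
    Site,
    TranscriptModel,
)

__all__ = [
    "SCALED_FEATURES",
    "COUNT_FEATURES",
    "CATEGORICAL_FEATURES",
    "MODEL_FEATURES",
    "OPTIONAL_FEATURES",
    "ScalingTable",
    "default_scaling_table",
    "target_site_abundance",
    "seed_pairing_stability",
    "local_au",
    "threep_score",
    "structural_accessibility",
    "min_dist",
    "scale_feature",
    "FeatureVector",
    "feature_vector",
    "expand_design_row",
    "design_columns",
]

#: continuous features subject to trimmed scaling
SCALED_FEATURES = (
    "TA_3UTR",
    "SPS",
    "Local_AU",
    "3P_score",
    "SA",
    "Min_dist",
    "P_CT",
    "Len_ORF",
    "Len_3UTR",
)
COUNT_FEATURES = ("Off6m", "ORF8m")
CATEGORICAL_FEATURES = ("sRNA1", "sRNA8", "site8")

#: the 14 features of the shipped model
MODEL_FEATURES = SCALED_FEATURES + COUNT_FEATURES + CATEGORICAL_FEATURES

#: additional candidate features available to the training module but
#: excluded from the shipped scoring model
OPTIONAL_FEATURES = (
    "TA_ORF",
    "dist_stop",
    "site1",
    "site9",
    "site10",
    "AU_5UTR",
    "AU_ORF",
    "AU_3UTR",
    "Len_5UTR",
    "ORF7m8",
    "ORF7A1",
    "ORF6m",
)

_M8_TYPES = (SITE_8MER, SITE_7M8)

# ---------------------------------------------------------------------------
# seed-pairing stability: embedded RNA nearest-neighbor stack table
# (Watson-Crick stacking free energies at 37 C, kcal/mol; Turner-style
# values, no duplex-initiation term).  Key = 5'->3' dinucleotide of the
# miRNA strand; the value already accounts for the complementary strand.
NN_STACK_KCAL = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}


def target_site_abundance(census_count: int) -> float:
    """TA_3UTR raw value: log10 of the transcriptome-wide seed-match count."""
    if census_count < 1:
        raise ValueError("family has no 3'-UTR seed matches in the transcriptome")
    return math.log10(census_count)


def seed_pairing_stability(member: str, site_type: str) -> float:
    """Predicted free energy (kcal/mol, 37 C) of a perfect seed:target helix:
    miRNA nt 2-8 for 8mer/7mer-m8 sites, nt 2-7 for 7mer-A1/6mer sites,
    summed over the embedded nearest-neighbor stack table.  More negative
    means more stable pairing."""
    if len(member) < 8:
        raise ValueError("mature sequence shorter than 8 nt")
    span = member[1:8] if site_type in _M8_TYPES else member[1:7]
    total = 0.0
    for a, b in zip(span, span[1:]):
        key = a + b
        if key not in NN_STACK_KCAL:
            raise ValueError(f"non-ACGU dinucleotide {key!r} in seed")
        total += NN_STACK_KCAL[key]
    return total


def local_au(utr3: str, site: Site, window: int = 30) -> float:
    """Distance-weighted A/U fraction of the sequence flanking the site.

    The k-th nucleotide from either site boundary carries weight 1/k over a
    ``window``-nt flank on each side; flanks truncated by the UTR ends are
    renormalized over the positions that exist.  Returns NaN if a flank
    contains N.
    """
    w_sum = 0.0
    au_sum = 0.0
    for k in range(1, window + 1):
        for pos in (site.start - k, site.end - 1 + k):
            if 0 <= pos < len(utr3):
                ch = utr3[pos]
                if ch == "N":
                    return float("nan")
                w = 1.0 / k
                w_sum += w
                if ch in "AU":
                    au_sum += w
    if w_sum == 0:
        return float("nan")
    return au_sum / w_sum


def threep_score(
    member: str,
    utr3: str,
    site: Site,
    *,
    target_region: int = 16,
    max_offset: int = 4,
    core_weight: float = 1.0,
    tail_weight: float = 0.5,
    offset_penalty: float = 0.5,
) -> float:
    """3'-supplementary pairing score.

    The miRNA 3' region (nt >= 9) is aligned against the ``target_region``
    nucleotides 5' of the seed pairing, sliding over offsets in
    [-max_offset, +max_offset].  The maximal-scoring contiguous Watson-Crick
    run is scored ``core_weight`` per pair involving miRNA nt 13-16 and
    ``tail_weight`` otherwise, minus ``offset_penalty * |offset|``; the
    maximum over runs and offsets is returned, floored at 0.
    """
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    # target index opposite miRNA nt 8 (one 5' of the site for A1/6mer types)
    anchor = site.start if site.site_type in _M8_TYPES else site.start - 1
    tail = member[8:]  # miRNA nt 9 onward, 5'->3'
    best = 0.0
    for off in range(-max_offset, max_offset + 1):
        for j in range(len(tail)):
            # start a run at miRNA nt 9+j
            run = 0.0
            for jj in range(j, len(tail)):
                t_idx = anchor - 1 - jj - off
                if t_idx < 0 or t_idx < anchor - target_region - off:
                    break
                if t_idx >= len(utr3) or comp.get(tail[jj]) != utr3[t_idx]:
                    break
                mir_pos = 9 + jj  # 1-based miRNA position
                run += core_weight if 13 <= mir_pos <= 16 else tail_weight
                best = max(best, run - offset_penalty * abs(off))
    return max(best, 0.0)


def sa_window(site: Site, utr_len: int, window: int = 14) -> tuple[int, int]:
    """The accessibility window: ``window`` nt centered on the two target
    nucleotides opposite miRNA positions 7 and 8, truncated at UTR ends."""
    if site.site_type in _M8_TYPES:
        # nt 8 pairs site.start, nt 7 pairs site.start + 1
        center_lo, center_hi = site.start, site.start + 1
    else:
        # nt 7 pairs site.start; nt 8 would pair one nt 5' of the site
        center_lo, center_hi = site.start - 1, site.start
    half = (window - 2) // 2
    lo = max(0, center_lo - half)
    hi = min(utr_len, center_hi + half + 1)
    return lo, hi


def structural_accessibility(utr3: str, site: Site, provider=None) -> float:
    """SA raw value: log10 probability that the 14-nt window centered on the
    match to miRNA positions 7-8 is unpaired under local folding."""
    if provider is None:
        provider = PartitionFunctionProvider()
    lo, hi = sa_window(site, len(utr3))
    p = provider.window_probability(utr3, lo, hi - lo)
    if not np.isfinite(p) or p <= 0:
        return float("nan")
    return math.log10(p)


def min_dist(site: Site, profile: IsoformProfile) -> float:
    """log10 of the distance between the site's closest edge and the nearer
    3'-UTR terminus (stop codon or polyadenylation site), clamped >= 1 and
    weighted across the tandem isoforms containing the site."""

    def per_isoform(end: int) -> float:
        d = min(site.start, end - site.end)
        return math.log10(max(d, 1))

    return weighted_feature(profile, site, per_isoform)


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScalingTable:
    """5th/95th percentile anchors per (feature, site type)."""

    table: dict[tuple[str, str], tuple[float, float]]

    def __post_init__(self) -> None:
        for key, (p5, p95) in self.table.items():
            if not p95 > p5:
                raise ValueError(f"{key}: p95 ({p95}) must exceed p5 ({p5})")

    def lookup(self, feature: str, site_type: str) -> tuple[float, float]:
        try:
            return self.table[(feature, site_type)]
        except KeyError:
            raise KeyError(f"no scaling entry for ({feature}, {site_type})") from None

    @classmethod
    def from_tsv(cls, path) -> "ScalingTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            {
                (r.feature, r.site_type): (float(r.p5), float(r.p95))
                for r in df.itertuples(index=False)
            }
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"feature": f, "site_type": t, "p5": p5, "p95": p95}
            for (f, t), (p5, p95) in sorted(self.table.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")


def default_scaling_table() -> ScalingTable:
    """The packaged scaling anchors (published training percentiles)."""
    with resources.files("contextpp.data").joinpath("scaling_defaults.tsv").open() as fh:
        return ScalingTable.from_tsv(fh)


def scale_feature(raw: float, feature: str, site_type: str, table: ScalingTable) -> float:
    """Trimmed normalization: (raw - p5) / (p95 - p5), not clipped.  Count
    and categorical features pass through untouched."""
    if feature in COUNT_FEATURES or feature in CATEGORICAL_FEATURES:
        return raw
    p5, p95 = table.lookup(feature, site_type)
    return (raw - p5) / (p95 - p5)


# ---------------------------------------------------------------------------
# the assembled vector


@dataclass
class FeatureVector:
    """Raw and scaled features for one site."""

    site: Site
    raw: dict[str, object]
    scaled: dict[str, object]

    @property
    def site_type(self) -> str:
        return self.site.site_type

    @property
    def scorable(self) -> bool:
        for name in MODEL_FEATURES:
            v = self.scaled.get(name)
            if v is None:
                return False
            if name not in CATEGORICAL_FEATURES and not np.isfinite(v):
                return False
        return True


def feature_vector(
    site: Site,
    transcript: TranscriptModel,
    family: MirnaFamily,
    member: str,
    profile: IsoformProfile,
    census: int,
    pct_lookup: Mapping | Callable | None = None,
    provider=None,
    *,
    scaling: ScalingTable | None = None,
    include_optional: bool = False,
) -> FeatureVector:
    """Assemble the (scaled) feature vector for one 3'-UTR site.

    ``pct_lookup`` maps (transcript_id, family_id, site start) to a P_CT
    probability; absent sites — and all sites of families that are not
    broadly conserved — get P_CT = 0.
    """
    if scaling is None:
        scaling = default_scaling_table()
    if provider is None:
        provider = PartitionFunctionProvider()
    utr3 = transcript.utr3
    sig = seed_signatures(family)

    raw: dict[str, object] = {}
    raw["TA_3UTR"] = target_site_abundance(census)
    raw["SPS"] = seed_pairing_stability(member, site.site_type)
    raw["Local_AU"] = local_au(utr3, site)
    raw["3P_score"] = threep_score(member, utr3, site)
    raw["SA"] = structural_accessibility(utr3, site, provider)
    raw["Min_dist"] = min_dist(site, profile)
    raw["Len_ORF"] = math.log10(max(len(transcript.orf), 1))
    raw["Len_3UTR"] = weighted_feature(
        profile, site, lambda end: math.log10(max(end, 1))
    )

    pct = 0.0
    if pct_lookup is not None and family.conservation_class == "broadly_conserved":
        key = (site.transcript_id, site.family_id, site.start)
        if callable(pct_lookup):
            pct = float(pct_lookup(*key) or 0.0)
        else:
            pct = float(pct_lookup.get(key, 0.0))
    raw["P_CT"] = pct

    # isoform-weighted offset-6mer count
    off6_starts = [
        s.start
        for s in find_sites(utr3, family, transcript_id=site.transcript_id)
        if s.site_type == SITE_OFF6
    ]
    raw["Off6m"] = weighted_feature(
        profile, site, lambda end: float(sum(1 for p in off6_starts if p + 6 <= end))
    )
    raw["ORF8m"] = float(count_orf_sites(transcript.orf, family)[SITE_8MER])

    raw["sRNA1"] = member[0]
    raw["sRNA8"] = member[7]
    site8_idx = site.start if site.site_type in _M8_TYPES else site.start - 1
    raw["site8"] = utr3[site8_idx] if 0 <= site8_idx < len(utr3) else "N"

    if include_optional:
        raw.update(_optional_features(site, transcript, family, utr3))

    scaled = {
        name: (
            scale_feature(value, name, site.site_type, scaling)
            if name in SCALED_FEATURES
            else value
        )
        for name, value in raw.items()
    }
    return FeatureVector(site=site, raw=raw, scaled=scaled)


def _optional_features(site, transcript, family, utr3) -> dict[str, object]:
    def au_frac(seq: str) -> float:
        if not seq:
            return float("nan")
        return sum(1 for c in seq if c in "AU") / len(seq)

    orf_counts = count_orf_sites(transcript.orf, family)
    out: dict[str, object] = {}
    orf_census = sum(orf_counts.values())
    out["TA_ORF"] = math.log10(orf_census) if orf_census >= 1 else 0.0
    out["dist_stop"] = math.log10(max(site.start, 1))
    out["site1"] = utr3[site.end - 1] if site.site_type in (SITE_8MER, SITE_7A1) else (
        utr3[site.end] if site.end < len(utr3) else "N"
    )
    idx9 = site.start - 1 if site.site_type in _M8_TYPES else site.start - 2
    idx10 = idx9 - 1
    out["site9"] = utr3[idx9] if 0 <= idx9 < len(utr3) else "N"
    out["site10"] = utr3[idx10] if 0 <= idx10 < len(utr3) else "N"
    out["AU_5UTR"] = au_frac(transcript.utr5)
    out["AU_ORF"] = au_frac(transcript.orf)
    out["AU_3UTR"] = au_frac(utr3)
    out["Len_5UTR"] = math.log10(max(len(transcript.utr5), 1))
    out["ORF7m8"] = float(orf_counts[SITE_7M8])
    out["ORF7A1"] = float(orf_counts[SITE_7A1])
    out["ORF6m"] = float(orf_counts[SITE_6MER])
    return out


# ---------------------------------------------------------------------------
# design-matrix expansion (categoricals -> A/C/G indicators, U reference)

_INDICATOR_NTS = ("A", "C", "G")


def design_columns(features=MODEL_FEATURES) -> list[str]:
    cols: list[str] = []
    for f in features:
        if f in CATEGORICAL_FEATURES or f in ("site1", "site9", "site10"):
            cols.extend(f"{f}_{nt}" for nt in _INDICATOR_NTS)
        else:
            cols.append(f)
    return cols


def expand_design_row(values: Mapping[str, object], features=MODEL_FEATURES) -> dict[str, float]:
    """Expand a feature mapping into numeric design-matrix entries, turning
    each nucleotide category into A/C/G indicator columns (U = reference;
    N contributes no indicator)."""
    row: dict[str, float] = {}
    for f in features:
        v = values[f]
        if f in CATEGORICAL_FEATURES or f in ("site1", "site9", "site10"):
            for nt in _INDICATOR_NTS:
                row[f"{f}_{nt}"] = 1.0 if v == nt else 0.0
        else:
            row[f] = float(v)
    return row
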