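"""3'-UTR tandem isoform profiles from 3P-seq clusters.

A profile lists the alternative cleavage-and-polyadenylation end positions
of a 3' UTR with their relative molecule abundances.  Per-dataset tag counts
are upper-quartile normalized before pooling; the longest tandem isoform
receives a pseudocount of 0.1 tag and the longest annotated isoform 5
pseudocounts, so every transcript has a profile even without tag support.

The profile yields, for each site, the affected isoform ratio (AIR): the
fraction of the gene's 3'-UTR molecules that contain the site.
"""
from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ClusterSet, IsoformProfile, Site, TranscriptModel

__all__ = [
    "upper_quartile_factors",
    "build_profile",
    "build_profiles",
    "air",
    "weighted_feature",
]


def upper_quartile_factors(
    clusters: ClusterSet,
    *,
    datasets: Sequence[str] | None = None,
    interpolation: str = "linear",
    relative: bool = True,
) -> dict[str, float]:
    """Per-dataset scale factor: the 75th percentile of per-transcript tag
    totals, over transcripts with >= 1 tag in that dataset (the edgeR
    'upperquartile' convention).

    With ``relative`` (default) factors are divided by their geometric mean,
    so they only rescale datasets against each other and the pooled counts
    keep the raw tag scale — the scale on which the fixed pseudocounts are
    defined.  A single dataset then has factor 1.
    """
    recs = clusters.records
    if datasets is not None:
        recs = recs[recs["dataset_id"].isin(datasets)]
    factors: dict[str, float] = {}
    for ds, grp in recs.groupby("dataset_id"):
        totals = grp.groupby("transcript_id")["tag_count"].sum()
        totals = totals[totals >= 1]
        if len(totals) == 0:
            factors[ds] = 1.0
        else:
            factors[ds] = float(np.percentile(totals, 75, method=interpolation))
    if relative and factors:
        logs = np.log([f for f in factors.values() if f > 0])
        gm = float(np.exp(logs.mean())) if len(logs) else 1.0
        factors = {ds: (f / gm if f > 0 else 1.0) for ds, f in factors.items()}
    return factors


def build_profile(
    transcript: TranscriptModel,
    clusters: ClusterSet,
    *,
    pseudocount_longest_tandem: float = 0.1,
    pseudocount_annotation: float = 5.0,
    datasets: Sequence[str] | None = None,
    uq_factors: Mapping[str, float] | None = None,
) -> IsoformProfile:
    """Build the tandem-isoform profile for one transcript.

    Tag counts are divided by the per-dataset upper-quartile factor and summed
    across datasets per cluster position.  The longest tandem isoform (most
    distal cluster, or the annotated end when no cluster reaches it) gets the
    0.1-tag pseudocount; the longest annotated isoform gets 5 pseudocounts.
    Abundances are normalized to sum to 1.

    ``datasets`` restricts the profile to a subset of 3P-seq datasets (e.g.
    a single developmental stage); the default pools everything.
    """
    utr_len = len(transcript.utr3)
    recs = clusters.for_transcript(transcript.transcript_id)
    if datasets is not None:
        recs = recs[recs["dataset_id"].isin(datasets)]
    if (recs["end_offset"] > utr_len).any():
        bad = recs.loc[recs["end_offset"] > utr_len, "end_offset"].tolist()
        raise ValueError(
            f"{transcript.transcript_id}: cluster end(s) {bad} beyond UTR length {utr_len}"
        )
    if uq_factors is None:
        uq_factors = upper_quartile_factors(clusters, datasets=datasets)

    weights: dict[int, float] = {}
    total_tags = float(recs["tag_count"].sum())
    for row in recs.itertuples(index=False):
        factor = uq_factors.get(row.dataset_id, 1.0)
        weights[int(row.end_offset)] = weights.get(int(row.end_offset), 0.0) + (
            row.tag_count / factor if factor > 0 else row.tag_count
        )

    # pseudocounts: longest tandem isoform, then longest annotated isoform
    longest_tandem = max(weights) if weights else utr_len
    if pseudocount_longest_tandem > 0:
        weights[longest_tandem] = weights.get(longest_tandem, 0.0) + pseudocount_longest_tandem
    if pseudocount_annotation > 0:
        weights[utr_len] = weights.get(utr_len, 0.0) + pseudocount_annotation
    if not weights:  # both pseudocounts disabled and no clusters
        raise ValueError(
            f"{transcript.transcript_id}: no clusters and pseudocounts disabled"
        )
    # the annotated end anchors the profile: the last end equals the
    # longest-annotation UTR length whenever it carries any weight
    ends = np.array(sorted(weights), dtype=int)
    ab = np.array([weights[e] for e in ends], dtype=float)
    ab /= ab.sum()
    return IsoformProfile(
        transcript_id=transcript.transcript_id,
        ends=ends,
        abundances=ab,
        total_tags=total_tags,
    )


def build_profiles(
    transcripts: Mapping[str, TranscriptModel],
    clusters: ClusterSet,
    **kwargs,
) -> dict[str, IsoformProfile]:
    uq = upper_quartile_factors(clusters, datasets=kwargs.get("datasets"))
    return {
        tid: build_profile(t, clusters, uq_factors=uq, **kwargs)
        for tid, t in transcripts.items()
    }


def air(profile: IsoformProfile, site: Site) -> float:
    """Affected isoform ratio: summed abundance of the isoforms whose end
    offset >= site.end (the site fully contained).  ORF sites are present in
    every isoform, so AIR = 1 by convention."""
    if site.region == "orf":
        return 1.0
    if site.transcript_id and profile.transcript_id and site.transcript_id != profile.transcript_id:
        raise ValueError(
            f"site transcript {site.transcript_id!r} != profile {profile.transcript_id!r}"
        )
    contained = profile.ends >= site.end
    return float(profile.abundances[contained].sum())


def weighted_feature(
    profile: IsoformProfile,
    site: Site,
    per_isoform_feature: Callable[[int], float],
) -> float:
    """Abundance-weighted mean of a per-isoform feature over the isoforms
    containing the site, with weights renormalized over those isoforms.

    Used for features that vary with 3'-UTR length: min_dist, len_3UTR and
    the offset-6mer count.
    """
    contained = profile.ends >= site.end
    w = profile.abundances[contained]
    if w.sum() <= 0 or not contained.any():
        raise ValueError("no isoform contains the site")
    vals = np.array([per_isoform_feature(int(e)) for e in profile.ends[contained]])
    return float(np.dot(w, vals) / w.sum())
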