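"""Per-site context++ scores, isoform weighting, and cumulative aggregation.

A site's context++ score (CS) is a per-site-type linear model over the 14
scaled features, bounded above by a site-type cap (-0.03, -0.02, -0.01 and 0
for 8mer, 7mer-m8, 7mer-A1 and 6mer sites), giving a piece-wise linear
function.  CS is in log2 fold-change units: 2**CS is the predicted fraction
of mRNA remaining due to that site.

Weighting by the affected isoform ratio (AIR) and aggregation over all
sites of a family on one 3'-UTR profile use the cumulative recursion

    C_i = C_{i-1} + (1 - 2**CS_i) (AIR_i - C_{i-1}),    C_0 = 0

over sites numbered from the distal end; the cumulative weighted context++
score (CWCS) is log2(1 - C_n).  This equals the log2 of the expected
remaining mRNA fraction when each tandem isoform independently carries the
sites it contains.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import (
    CATEGORICAL_FEATURES,
    MODEL_FEATURES,
    FeatureVector,
    ScalingTable,
    default_scaling_table,
    expand_design_row,
    feature_vector,
)
from .profiles import air as compute_air
from .sites import find_sites, target_site_census
from .types import (
    CANONICAL_SITE_TYPES,
    SITE_6MER,
    IsoformProfile,
    MirnaFamily,
    Site,
    TranscriptModel,
)

__all__ = [
    "DEFAULT_CAPS",
    "SiteTypeModel",
    "ContextModel",
    "load_default_model",
    "ScoredSite",
    "context_score",
    "site_weighted_score",
    "cumulative_weighted_score",
    "score_sites",
    "family_transcript_score",
    "rank_predictions",
]

DEFAULT_CAPS = {"8mer": -0.03, "7mer-m8": -0.02, "7mer-A1": -0.01, "6mer": 0.0}


@dataclass
class SiteTypeModel:
    """Linear scoring model for one site type: intercept, coefficients over
    the expanded design columns, and the score cap."""

    site_type: str
    intercept: float
    coefficients: dict[str, float]
    cap: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cap is None:
            self.cap = DEFAULT_CAPS[self.site_type]


@dataclass
class ContextModel:
    """The four per-site-type models plus their scaling table."""

    site_models: dict[str, SiteTypeModel]
    scaling: ScalingTable = field(default_factory=default_scaling_table)

    def __getitem__(self, site_type: str) -> SiteTypeModel:
        return self.site_models[site_type]

    def __contains__(self, site_type: str) -> bool:
        return site_type in self.site_models

    @classmethod
    def from_tsv(cls, path, scaling: ScalingTable | None = None) -> "ContextModel":
        df = pd.read_csv(path, sep="\t", comment="#")
        models: dict[str, SiteTypeModel] = {}
        for st, grp in df.groupby("site_type"):
            terms = dict(zip(grp["term"], grp["value"].astype(float)))
            intercept = terms.pop("intercept")
            cap = terms.pop("cap", DEFAULT_CAPS[st])
            models[st] = SiteTypeModel(
                site_type=st, intercept=intercept, coefficients=terms, cap=cap
            )
        return cls(site_models=models, scaling=scaling or default_scaling_table())

    def to_tsv(self, path) -> None:
        rows = []
        for st, m in self.site_models.items():
            rows.append({"site_type": st, "term": "intercept", "value": m.intercept})
            rows.append({"site_type": st, "term": "cap", "value": m.cap})
            rows.extend(
                {"site_type": st, "term": t, "value": v}
                for t, v in m.coefficients.items()
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_default_model() -> ContextModel:
    """The packaged coefficient configuration.

    The shipped table was trained on the synthetic compendium (see the file
    header); it covers exactly the 14 model features per site type.
    """
    with resources.files("contextpp.data").joinpath("coefficients_synthetic.tsv").open() as fh:
        return ContextModel.from_tsv(fh)


@dataclass
class ScoredSite:
    site: Site
    cs: float
    air: float
    features: FeatureVector | None = None

    @property
    def wcs(self) -> float:
        return site_weighted_score(self.cs, self.air)


def context_score(fv: FeatureVector, model: SiteTypeModel) -> float:
    """CS = min(cap, intercept + sum coef * scaled feature)."""
    row = expand_design_row(fv.scaled, MODEL_FEATURES)
    total = model.intercept
    for term, coef in model.coefficients.items():
        if term not in row:
            raise KeyError(f"model term {term!r} missing from feature vector")
        total += coef * row[term]
    return min(model.cap, total)


def site_weighted_score(cs: float, air: float) -> float:
    """Weighted context++ score: log2(1 - AIR * (1 - 2**CS)).

    With AIR = 1 this is CS itself; with AIR = 0 the site is absent from
    every isoform and contributes nothing.
    """
    if not 0.0 <= air <= 1.0:
        raise ValueError(f"AIR must be in [0,1], got {air}")
    return math.log2(1.0 - air * (1.0 - 2.0 ** cs))


def cumulative_weighted_score(sites: Sequence[ScoredSite]) -> float:
    """CWCS over sites ordered distal -> proximal (AIR nondecreasing).

    Applies C_i = C_{i-1} + (1 - 2**CS_i)(AIR_i - C_{i-1}) with C_0 = 0 and
    returns log2(1 - C_n).  An AIR ordering violation indicates mis-sorted
    sites and raises.
    """
    c = 0.0
    prev_air = -1.0
    for s in sites:
        if s.air < prev_air - 1e-12:
            raise ValueError("sites must be ordered distal->proximal (AIR nondecreasing)")
        prev_air = s.air
        c = c + (1.0 - 2.0 ** s.cs) * (s.air - c)
    return math.log2(1.0 - c)


def score_sites(
    transcript: TranscriptModel,
    family: MirnaFamily,
    member: str,
    profile: IsoformProfile,
    model: ContextModel,
    census: int,
    pct_lookup=None,
    provider=None,
    *,
    exclude_ribosome_shadow: bool = True,
) -> list[ScoredSite]:
    """Score every canonical site of one family member on one transcript."""
    sites = find_sites(
        transcript.utr3,
        family,
        transcript_id=transcript.transcript_id,
        exclude_ribosome_shadow=exclude_ribosome_shadow,
    )
    out = []
    for site in sites:
        if site.site_type not in model:
            continue  # offset-6mers contribute as a feature, not as scored sites
        fv = feature_vector(
            site,
            transcript,
            family,
            member,
            profile,
            census,
            pct_lookup,
            provider,
            scaling=model.scaling,
        )
        if not fv.scorable:
            continue
        cs = context_score(fv, model[site.site_type])
        out.append(ScoredSite(site=site, cs=cs, air=compute_air(profile, site), features=fv))
    return out


def family_transcript_score(
    transcript: TranscriptModel,
    family: MirnaFamily,
    profile: IsoformProfile,
    model: ContextModel,
    census: int,
    pct_lookup=None,
    provider=None,
    **kwargs,
) -> dict | None:
    """CWCS of one family on one transcript.

    CWCS is computed per mature member and the member with the greatest
    predicted repression (minimum CWCS) represents the family.  Returns None
    when the transcript has no scorable canonical site.
    """
    best = None
    for member in family.members:
        scored = score_sites(
            transcript, family, member, profile, model, census, pct_lookup, provider, **kwargs
        )
        if not scored:
            continue
        # distal end first: larger start offsets are closer to the 3' end of
        # the longest isoform, hence present in fewer isoforms (smaller AIR)
        scored.sort(key=lambda s: -s.site.start)
        cwcs = cumulative_weighted_score(scored)
        if best is None or cwcs < best["cwcs"]:
            best = {
                "transcript_id": transcript.transcript_id,
                "gene_id": transcript.gene_id,
                "family_id": family.family_id,
                "member": member,
                "cwcs": cwcs,
                "sites": scored,
                "total_tags": profile.total_tags,
            }
    return best


def representative_records(records: Iterable[dict]) -> list[dict]:
    """Per (gene, family), keep the record of the transcript with the most
    3P-seq tags (the gene's representative 3'-UTR profile)."""
    best: dict[tuple[str, str], dict] = {}
    for rec in records:
        key = (rec["gene_id"], rec["family_id"])
        cur = best.get(key)
        if cur is None or rec["total_tags"] > cur["total_tags"]:
            best[key] = rec
    return list(best.values())


def rank_predictions(records: Iterable[dict], *, only_7_8mer_listing: bool = True) -> pd.DataFrame:
    """Ranked prediction table, most repressive (most negative CWCS) first.

    Targets whose only canonical sites are 6mers are excluded from the
    listing (their contribution remains inside CWCS wherever they co-occur
    with stronger sites).  The score percentile of a prediction is 100x the
    fraction of same-family predictions that are equally or less repressive,
    so the best prediction of a family sits at percentile 100.
    """
    records = list(records)
    rows = []
    for rec in records:
        has_78 = any(s.site.site_type != SITE_6MER for s in rec["sites"])
        if only_7_8mer_listing and not has_78:
            continue
        rows.append(
            {
                "transcript_id": rec["transcript_id"],
                "gene_id": rec["gene_id"],
                "family_id": rec["family_id"],
                "member": rec["member"],
                "n_sites": len(rec["sites"]),
                "cwcs": rec["cwcs"],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "family_id", "member", "n_sites", "cwcs"],
    )
    if df.empty:
        df["percentile"] = pd.Series(dtype=float)
        return df
    pct = np.empty(len(df))
    for fam, grp in df.groupby("family_id"):
        scores = grp["cwcs"].to_numpy()
        for idx, c in zip(grp.index, scores):
            pct[idx] = 100.0 * np.mean(scores >= c)
    df["percentile"] = pct
    df = df.sort_values(["cwcs", "transcript_id"], kind="mergesort").reset_index(drop=True)
    return df
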