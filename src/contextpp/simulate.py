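"""Synthetic data with the statistical structure the model assumes.

Three generators cover the inputs of the whole pipeline:

* :func:`simulate_transcriptome` — random mRNAs with canonical sites planted
  at controlled type frequencies (UTRs are scrubbed of spurious seed matches
  first, so the planted registry is the complete ground truth);
* :func:`simulate_profiles` — 1-4 tandem 3'-UTR ends per transcript with
  multinomial 3P-seq tag counts across datasets;
* :func:`simulate_compendium` — a fold-change compendium in which each
  experiment perturbs one family: per-gene response = sum of planted linear
  per-site effects + a low-rank batch component tied to gene covariates
  (3'-UTR length, AU content; studies share loadings, emulating
  protocol-dependent biases) + iid Gaussian noise.

Defaults state a human-like desk-scale world: ~1 kb log-normal 3' UTRs,
GC 0.4, 100 tags per transcript per 3P-seq dataset, noise SD 0.1 log2
units, rank-2 batch structure.  Everything is deterministic under the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import MODEL_FEATURES, default_scaling_table, expand_design_row, feature_vector
from .profiles import build_profiles
from .scoring import ContextModel, SiteTypeModel
from .sites import RIBOSOME_SHADOW_NT, find_sites, seed_signatures, target_site_census
from .types import (
    CANONICAL_SITE_TYPES,
    SITE_6MER,
    SITE_7A1,
    SITE_7M8,
    SITE_8MER,
    SITE_OFF6,
    ClusterSet,
    FoldChangeCompendium,
    MirnaFamily,
    Site,
    TranscriptModel,
)

__all__ = [
    "SimulationConfig",
    "simulate_transcriptome",
    "simulate_profiles",
    "simulate_compendium",
    "default_truth_model",
    "SimulatedCompendium",
]

NTS = np.array(list("ACGU"))


@dataclass
class SimulationConfig:
    n_transcripts: int = 200
    utr3_log10_mean: float = 3.0  # median ~1 kb
    utr3_log10_sd: float = 0.25
    orf_len: int = 900
    utr5_len: int = 150
    gc_content: float = 0.40
    n_mirnas: int = 5
    n_experiments: int = 5
    site_type_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            SITE_8MER: 0.25,
            SITE_7M8: 0.25,
            SITE_7A1: 0.25,
            SITE_6MER: 0.25,
        }
    )
    plant_prob: float = 0.8  # chance a transcript gets >= 1 site
    max_sites_per_utr: int = 2
    offset6_rate: float = 0.5  # chance of planting 1-2 decoy offset-6mers
    orf8_rate: float = 0.3  # chance of planting 1-2 ORF 8mer sites
    n_isoforms_max: int = 4
    n_3pseq_datasets: int = 3
    tag_depth: int = 100
    noise_sd: float = 0.10
    batch_rank: int = 2
    batch_sd: float = 0.0  # per-study loading SD, in log2 units; 0 disables
    n_studies: int = 3
    endogenous_derepression: float = 0.0  # optional positive offset magnitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1 or self.n_mirnas < 1 or self.n_experiments < 1:
            raise ValueError("counts must be >= 1")
        if self.n_experiments > self.n_mirnas:
            raise ValueError("each experiment perturbs a distinct family")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(NTS, size=length, p=p))


def _scrub(seq: str, forbidden: Sequence[str], rng: np.random.Generator) -> str:
    """Mutate single positions until no forbidden k-mer occurs."""
    s = list(seq)
    for _ in range(20 * len(seq) + 100):
        text = "".join(s)
        hit = None
        for kmer in forbidden:
            i = text.find(kmer)
            if i != -1:
                hit = (i, len(kmer))
                break
        if hit is None:
            return text
        i, k = hit
        j = int(rng.integers(i, i + k))
        s[j] = str(rng.choice(NTS[NTS != s[j]]))
    raise RuntimeError("could not scrub sequence of seed matches")


def _random_families(rng: np.random.Generator, n: int) -> dict[str, MirnaFamily]:
    fams: dict[str, MirnaFamily] = {}
    seeds: set[str] = set()
    while len(fams) < n:
        seed = "".join(rng.choice(NTS, size=7))
        if seed in seeds:
            continue
        seeds.add(seed)
        tail = "".join(rng.choice(NTS, size=14))
        member = str(rng.choice(NTS)) + seed + tail  # 22-nt mature sRNA
        fid = f"fam{len(fams):02d}"
        fams[fid] = MirnaFamily(
            family_id=fid,
            seed7=seed,
            members=(member,),
            conservation_class="broadly_conserved",
        )
    return fams


def simulate_transcriptome(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, TranscriptModel], dict[str, MirnaFamily], pd.DataFrame]:
    """Random transcriptome with planted canonical sites.

    Returns (transcripts, families, registry); the registry lists every
    planted site (transcript_id, family_id, site_type, start, end) and is
    exactly what site discovery recovers, because UTR and ORF sequences are
    scrubbed of all spurious seed matches before planting.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    families = _random_families(rng, config.n_mirnas)
    sigs = {fid: seed_signatures(f) for fid, f in families.items()}
    # forbid the 6mer core and offset-6mer of every family
    forbidden = sorted(
        {s.site_6mer for s in sigs.values()} | {s.site_offset_6mer for s in sigs.values()}
    )
    type_names = list(config.site_type_probs)
    type_p = np.array([config.site_type_probs[t] for t in type_names], dtype=float)
    type_p = type_p / type_p.sum()

    transcripts: dict[str, TranscriptModel] = {}
    registry_rows = []
    for i in range(config.n_transcripts):
        tid = f"tx{i:04d}"
        gid = f"g{i:04d}"
        utr_len = int(
            np.clip(10 ** rng.normal(config.utr3_log10_mean, config.utr3_log10_sd), 80, 8000)
        )
        for attempt in range(50):
            utr5 = _random_seq(rng, config.utr5_len, config.gc_content)
            orf = _scrub(_random_seq(rng, config.orf_len, config.gc_content), forbidden, rng)
            utr3 = _scrub(_random_seq(rng, utr_len, config.gc_content), forbidden, rng)
            planted = []
            if rng.random() < config.plant_prob:
                fam_id = str(rng.choice(list(families)))
                n_sites = int(rng.integers(1, config.max_sites_per_utr + 1))
                utr3, planted = _plant_sites(
                    utr3, families[fam_id], sigs[fam_id], n_sites, type_names, type_p, rng,
                    offset6_rate=config.offset6_rate,
                )
                if rng.random() < config.orf8_rate:
                    orf = _plant_orf_8mers(
                        orf, sigs[fam_id], int(rng.integers(1, 3)), rng
                    )
            # verify the registry is exactly recoverable
            found = {
                (s.family_id, s.site_type, s.start, s.end)
                for fid, fam in families.items()
                for s in find_sites(utr3, fam, transcript_id=tid)
                if s.site_type != SITE_OFF6
            }
            expect = {(f, t, s, e) for (f, t, s, e) in planted}
            if found == expect:
                break
        else:
            raise RuntimeError(f"{tid}: could not plant sites cleanly")
        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=gid, utr5=utr5, orf=orf, utr3=utr3
        )
        registry_rows.extend(
            {
                "transcript_id": tid,
                "family_id": f,
                "site_type": t,
                "start": s,
                "end": e,
            }
            for (f, t, s, e) in planted
        )
    registry = pd.DataFrame(
        registry_rows, columns=["transcript_id", "family_id", "site_type", "start", "end"]
    )
    return transcripts, families, registry


def _plant_sites(utr3, family, sig, n_sites, type_names, type_p, rng, *, offset6_rate=0.0):
    """Write site signatures into the UTR at non-overlapping positions
    outside the ribosome shadow, pinning the flanking nucleotides so the
    planted type is also the classified type.  Optionally also plants decoy
    offset-6mer occurrences (they feed the Off6m feature)."""
    sig_map = sig.as_dict()
    m8_char = sig.site_7mer_m8[0]
    before_choices = [c for c in "ACGU" if c != m8_char]
    seq = list(utr3)
    occupied: list[tuple[int, int]] = []
    planted = []
    for _ in range(n_sites):
        st = str(rng.choice(type_names, p=type_p))
        kmer = sig_map[st]
        k = len(kmer)
        lo = RIBOSOME_SHADOW_NT + 1
        hi = len(seq) - k - 1
        if hi <= lo:
            break
        for _try in range(100):
            p = int(rng.integers(lo, hi))
            if all(p + k + 2 <= s or p >= e + 2 for s, e in occupied):
                break
        else:
            continue
        seq[p : p + k] = list(kmer)
        seq[p - 1] = str(rng.choice(before_choices))  # no accidental m8 extension
        if seq[p + k] == "A":
            seq[p + k] = "C"  # no accidental A1 extension
        occupied.append((p, p + k))
        planted.append((family.family_id, st, p, p + k))
    if offset6_rate > 0 and rng.random() < offset6_rate:
        off6 = sig_map[SITE_OFF6]
        # the char completing a 7mer-m8 out of the offset-6mer prefix
        completing = sig.site_7mer_m8[6]
        after_choices = [c for c in "CGU" if c != completing] or ["G"]
        for _ in range(int(rng.integers(1, 3))):
            lo, hi = RIBOSOME_SHADOW_NT + 1, len(seq) - 8
            if hi <= lo:
                break
            for _try in range(100):
                p = int(rng.integers(lo, hi))
                if all(p + 8 <= s or p >= e + 2 for s, e in occupied):
                    break
            else:
                continue
            seq[p : p + 6] = list(off6)
            seq[p + 6] = str(rng.choice(after_choices))
            occupied.append((p, p + 6))
    return "".join(seq), sorted(planted, key=lambda x: x[2])


def _plant_orf_8mers(orf: str, sig, n: int, rng) -> str:
    """Plant 8mer signatures into the ORF (they feed the ORF8m feature)."""
    kmer = sig.site_8mer
    seq = list(orf)
    occupied: list[tuple[int, int]] = []
    for _ in range(n):
        if len(seq) < 30:
            break
        for _try in range(100):
            p = int(rng.integers(3, len(seq) - 11))
            if all(p + 10 <= s or p >= e + 2 for s, e in occupied):
                break
        else:
            continue
        seq[p : p + 8] = list(kmer)
        occupied.append((p, p + 8))
    return "".join(seq)


def simulate_profiles(
    transcripts: Mapping[str, TranscriptModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ClusterSet, pd.DataFrame]:
    """Tandem-isoform truth and 3P-seq tags.

    Each transcript gets 1-4 ends (the last at the annotated UTR end) with
    Dirichlet abundances; each dataset observes multinomial tag counts of
    total ``tag_depth``.  Returns (clusters, truth) where truth has columns
    transcript_id, end_offset, abundance.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    cluster_rows = []
    truth_rows = []
    datasets = [f"ds{d}" for d in range(config.n_3pseq_datasets)]
    for tid, t in transcripts.items():
        utr_len = len(t.utr3)
        n_iso = int(rng.integers(1, config.n_isoforms_max + 1))
        if utr_len < 40 * n_iso:
            n_iso = 1
        ends = sorted(
            rng.choice(np.arange(30, utr_len - 20), size=n_iso - 1, replace=False).tolist()
        ) + [utr_len] if n_iso > 1 else [utr_len]
        ab = rng.dirichlet(np.ones(n_iso))
        for e, a in zip(ends, ab):
            truth_rows.append({"transcript_id": tid, "end_offset": int(e), "abundance": float(a)})
        for ds in datasets:
            if config.tag_depth > 0:
                counts = rng.multinomial(config.tag_depth, ab)
                for e, c in zip(ends, counts):
                    if c > 0:
                        cluster_rows.append(
                            {
                                "transcript_id": tid,
                                "end_offset": int(e),
                                "tag_count": int(c),
                                "dataset_id": ds,
                            }
                        )
    clusters = ClusterSet(
        records=pd.DataFrame(
            cluster_rows, columns=["transcript_id", "end_offset", "tag_count", "dataset_id"]
        )
    )
    truth = pd.DataFrame(truth_rows, columns=["transcript_id", "end_offset", "abundance"])
    return clusters, truth


def default_truth_model() -> ContextModel:
    """A plausible ground-truth linear model for simulation: repression
    strongest for 8mers, coefficient signs as established for each feature
    (longer UTR/ORF protect; accessibility, local AU, 3'-pairing, seed
    stability and conservation repress).  Caps are disabled (set to +inf)
    so the simulated response is exactly linear."""
    base_coefs = {
        "TA_3UTR": 0.06,
        "SPS": 0.06,
        "Local_AU": -0.06,
        "3P_score": -0.04,
        "SA": -0.07,
        "Min_dist": 0.05,
        "P_CT": -0.04,
        "Len_ORF": 0.05,
        "Len_3UTR": 0.06,
        "Off6m": -0.005,
        "ORF8m": -0.01,
        "sRNA1_A": -0.01,
        "sRNA1_C": 0.005,
        "sRNA1_G": -0.02,
        "sRNA8_A": -0.01,
        "sRNA8_C": 0.01,
        "sRNA8_G": 0.0,
        "site8_A": -0.005,
        "site8_C": 0.01,
        "site8_G": 0.0,
    }
    intercepts = {SITE_8MER: -0.28, SITE_7M8: -0.18, SITE_7A1: -0.10, SITE_6MER: -0.04}
    strength = {SITE_8MER: 1.0, SITE_7M8: 0.8, SITE_7A1: 0.5, SITE_6MER: 0.3}
    models = {
        st: SiteTypeModel(
            site_type=st,
            intercept=intercepts[st],
            coefficients={k: v * strength[st] for k, v in base_coefs.items()},
            cap=float("inf"),
        )
        for st in CANONICAL_SITE_TYPES
    }
    return ContextModel(site_models=models, scaling=default_scaling_table())


@dataclass
class SimulatedCompendium:
    compendium: FoldChangeCompendium
    signal: pd.DataFrame  # planted per-gene site effects (genes x experiments)
    batch: pd.DataFrame  # planted batch component
    experiment_families: dict[str, str]
    site_rows: pd.DataFrame  # one row per (gene, experiment, site): design + effect
    profiles: dict | None = None
    census: dict | None = None
    pct_lookup: dict | None = None


def simulate_compendium(
    transcripts: Mapping[str, TranscriptModel],
    families: Mapping[str, MirnaFamily],
    truth_model: ContextModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    profiles=None,
    census: Mapping[str, int] | None = None,
    pct_lookup: Mapping | None = None,
) -> SimulatedCompendium:
    """Fold-change compendium with planted linear site effects.

    Experiment k perturbs family k; a gene's fold change is the summed
    per-site effect of the truth model on the computed scaled features, plus
    the batch component, plus noise.  The mask T marks genes with a 7-8 nt
    canonical site to the perturbed family.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    fam_ids = list(families)[: config.n_experiments]
    exp_ids = [f"exp_{fid}" for fid in fam_ids]
    gene_ids = list(transcripts)
    if profiles is None:
        clusters, _ = simulate_profiles(transcripts, config, rng)
        profiles = build_profiles(transcripts, clusters)
    if census is None:
        census = {
            fid: max(target_site_census(transcripts, families[fid]), 1) for fid in fam_ids
        }
    if pct_lookup is None:
        # synthetic conservation probabilities: roughly half the sites carry
        # a nonzero P_CT drawn uniformly below the published 8mer p95
        pct_lookup = {}
        for fid in fam_ids:
            fam = families[fid]
            for tid, t in transcripts.items():
                for s in find_sites(t.utr3, fam, transcript_id=tid):
                    if s.site_type != SITE_OFF6 and rng.random() < 0.5:
                        pct_lookup[(tid, fid, s.start)] = float(rng.uniform(0.0, 0.8))

    signal = pd.DataFrame(0.0, index=gene_ids, columns=exp_ids)
    T = pd.DataFrame(0, index=gene_ids, columns=exp_ids)
    site_rows = []
    for fid, eid in zip(fam_ids, exp_ids):
        fam = families[fid]
        member = fam.members[0]
        for tid, t in transcripts.items():
            sites = [
                s
                for s in find_sites(
                    t.utr3, fam, transcript_id=tid, exclude_ribosome_shadow=True
                )
                if s.site_type != SITE_OFF6
            ]
            if not sites:
                continue
            if any(s.site_type != SITE_6MER for s in sites):
                T.loc[tid, eid] = 1
            total = 0.0
            for s in sites:
                fv = feature_vector(
                    s, t, fam, member, profiles[tid], census[fid], pct_lookup,
                    scaling=truth_model.scaling,
                )
                if not fv.scorable:
                    continue
                row = expand_design_row(fv.scaled, MODEL_FEATURES)
                m = truth_model[s.site_type]
                effect = m.intercept + sum(
                    m.coefficients.get(k, 0.0) * v for k, v in row.items()
                )
                total += effect
                site_rows.append(
                    {
                        "gene_id": tid,
                        "experiment_id": eid,
                        "site_type": s.site_type,
                        "effect": effect,
                        **row,
                    }
                )
            signal.loc[tid, eid] = total

    # low-rank batch component tied to gene covariates, shared within studies
    batch = pd.DataFrame(0.0, index=gene_ids, columns=exp_ids)
    if config.batch_sd > 0 and config.batch_rank > 0:
        covs = []
        lens = np.array([np.log10(len(t.utr3)) for t in transcripts.values()])
        aus = np.array(
            [sum(1 for c in t.utr3 if c in "AU") / len(t.utr3) for t in transcripts.values()]
        )
        for r, cov in enumerate([lens, aus][: config.batch_rank]):
            u = (cov - cov.mean()) / (cov.std() + 1e-12)
            study = rng.integers(0, config.n_studies, size=len(exp_ids))
            study_load = rng.normal(0.0, config.batch_sd, size=config.n_studies)
            v = study_load[study] + rng.normal(0.0, 0.1 * config.batch_sd, size=len(exp_ids))
            batch += pd.DataFrame(np.outer(u, v), index=gene_ids, columns=exp_ids)

    Z = signal + batch + rng.normal(0.0, config.noise_sd, size=signal.shape)
    if config.endogenous_derepression > 0:
        # genes with sites to the first family behave as endogenous targets
        endo = T.iloc[:, 0] == 1
        Z.loc[endo, :] += config.endogenous_derepression

    comp = FoldChangeCompendium(Z=Z, T=T)
    return SimulatedCompendium(
        compendium=comp,
        signal=signal,
        batch=batch,
        experiment_families=dict(zip(exp_ids, fam_ids)),
        site_rows=pd.DataFrame(site_rows),
        profiles=dict(profiles),
        census=dict(census),
        pct_lookup=dict(pct_lookup),
    )
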