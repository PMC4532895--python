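"""Regenerate the packaged coefficient table.

The published coefficient release for the context++ model is not
redistributable here, so the shipped table is trained on the synthetic
compendium: simulate a transcriptome with planted sites, fold changes with
batch structure and noise, run PLSR normalization, and fit the per-site-type
OLS models on the 14 model features of single-site genes.  Writes
src/contextpp/data/coefficients_synthetic.tsv (labeled synthetic).

Usage: python scripts/make_shipped_model.py [--seed 20150812]
"""
from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from contextpp.features import design_columns
from contextpp.normalization import normalize_compendium
from contextpp.scoring import ContextModel
from contextpp.simulate import (
    SimulationConfig,
    default_truth_model,
    simulate_compendium,
    simulate_transcriptome,
)
from contextpp.training import (
    drop_aliased_columns,
    fit_site_model,
    training_set_from_simulation,
)

HEADER = (
    "# SYNTHETIC coefficients: per-site-type OLS fit of the 14 model features\n"
    "# on a simulated single-site training compendium (see scripts/make_shipped_model.py).\n"
    "# These are stand-ins for a published coefficient release, not estimates from\n"
    "# experimental data.\n"
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20150812 % (2**31))
    ap.add_argument(
        "--out",
        default=Path(__file__).resolve().parents[1]
        / "src/contextpp/data/coefficients_synthetic.tsv",
    )
    args = ap.parse_args()

    config = SimulationConfig(
        n_transcripts=2400,
        n_mirnas=16,
        n_experiments=16,
        batch_sd=0.3,
        noise_sd=0.10,
        seed=args.seed,
    )
    truth = default_truth_model()
    transcripts, families, _ = simulate_transcriptome(config)
    sim = simulate_compendium(transcripts, families, truth, config)
    norm = normalize_compendium(sim.compendium)
    training = training_set_from_simulation(sim, responses=norm.Z_norm)

    models = {}
    for st, (X, y, _) in training.per_type.items():
        cols = drop_aliased_columns(X[design_columns()])
        model, ci = fit_site_model(X[cols], y, st)
        # aliased columns (e.g. site8 of m8-matched types, which duplicates
        # sRNA8) keep coefficient 0, so the shipped file covers all 14
        # features for every site type
        for c in design_columns():
            model.coefficients.setdefault(c, 0.0)
        model.coefficients = {c: model.coefficients[c] for c in design_columns()}
        models[st] = model
        print(f"{st}: n={len(y)} intercept={model.intercept:+.3f}")

    out = Path(args.out)
    tmp = out.with_suffix(".tmp")
    ContextModel(site_models=models).to_tsv(tmp)
    out.write_text(HEADER + tmp.read_text())
    tmp.unlink()
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
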