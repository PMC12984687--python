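#!/usr/bin/env python
"""Compare the fitted models: DIC / pD / Mean(L), genetic parameters, EBVs.

Reads the saved posterior draws, recomputes the comparison criteria, prints
the model-comparison table and the heritability/correlation summary of the
baseline model, and writes results/comparison.json plus trace plots.
"""

import argparse
import json
from pathlib import Path

from semsire import (
    build_designs,
    dic,
    ebv_correlations,
    load_samples,
    nellore_default_plan,
    read_phenotypes,
    summarize_genetic_params,
)
from semsire.comparison import comparison_table, convergence_diagnostics, plot_traces

MODELS = ["SMTM", "FA2F", "FA3F", "FA2G", "FA2R", "FRM", "REC1", "REC2"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--fitdir", type=Path, default=Path("results/fits"))
    parser.add_argument("--out", type=Path, default=Path("results/comparison.json"))
    args = parser.parse_args()

    tbl = read_phenotypes(args.datadir / "phenotypes.csv")
    designs = build_designs(tbl, nellore_default_plan())
    available = [m for m in MODELS if (args.fitdir / m).exists()]
    loaded = {m: load_samples(args.fitdir / m) for m in available}

    results = {m: dic(s, designs) for m, s in loaded.items()}
    table = comparison_table(results)
    print("model comparison (lower DIC is better):")
    print(table.to_string(float_format=lambda v: f"{v:,.1f}"))

    report = {"criteria": table.to_dict(orient="index"), "ebv_correlations": {}}
    base = loaded[available[0]]
    for m in available[1:]:
        corr = ebv_correlations(base, loaded[m])
        report["ebv_correlations"][f"{available[0]}~{m}"] = corr.to_dict(orient="index")
        print(f"\nEBV correlations {available[0]} ~ {m}:")
        print(corr.to_string(float_format=lambda v: f"{v:.3f}"))

    summary = summarize_genetic_params(base)
    print(f"\n{available[0]}: heritability (diagonal), genetic (above) and "
          "residual (below) correlations, posterior means:")
    print(summary["mean"].to_string(float_format=lambda v: f"{v:.2f}"))
    report["baseline_summary_mean"] = summary["mean"].to_dict()
    report["baseline_summary_sd"] = summary["sd"].to_dict()

    diag = convergence_diagnostics(base)
    print(f"\nminimum ESS across variance-component chains: {diag['ess'].min():.0f}")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=1))
    plot_traces(base, args.out.parent / "traces_baseline.png")


if __name__ == "__main__":
    main()
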