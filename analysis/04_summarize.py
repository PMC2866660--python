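"""Reduce the sweep outputs to the study's headline comparisons:

* average transformation counts against the prior mean at each confidence
  level (the prior never stops mattering for the averages);
* the most probable character history per cell (prior-invariant for the
  homoplasy-free character, prior-dependent for the homoplastic one);
* where the rate sampling concentrates under the diffuse priors.

Run analysis/03_run_sweep.py first.
"""

import os

import pandas as pd

SWEEP = "results/sweep"


def main():
    summary = pd.read_csv(os.path.join(SWEEP, "summary.tsv"), sep="\t")
    print("== average transformations (rows: E(T); columns: SD(T)) ==")
    for name, block in summary.groupby("character"):
        print("\ncharacter:", name)
        print(
            block.pivot(index="E_T", columns="SD_T", values="mean_total").round(2)
        )

    print("\n== most probable character history per cell ==")
    rows = []
    for name in sorted(summary["character"].unique()):
        for _, row in summary[summary["character"] == name].iterrows():
            tag = "%s_%g_%g" % (name, row["E_T"], row["SD_T"])
            top = pd.read_csv(os.path.join(SWEEP, tag + "_ppc_top.tsv"), sep="\t").iloc[0]
            rows.append(
                (name, row["E_T"], row["SD_T"], int(top["n01"]), int(top["n10"]), top["ppc"])
            )
    table = pd.DataFrame(rows, columns=["character", "E_T", "SD_T", "n01", "n10", "PPc"])
    print(table.to_string(index=False))

    print("\n== modal sampled rate value under SD(T)=5 ==")
    for name in sorted(summary["character"].unique()):
        for e in (1, 5, 10, 15):
            cats = pd.read_csv(
                os.path.join(SWEEP, "%s_%g_5_categories.tsv" % (name, e)), sep="\t"
            )
            modal = cats.loc[cats["count"].idxmax()]
            print(
                "  %-5s E=%-3g modal category %2d  rate value %.3g  (sampled %d/10000)"
                % (name, e, modal["category"], modal["representative"], modal["count"])
            )

    print("\nparsimony reference rows:")
    print(pd.read_csv(os.path.join(SWEEP, "parsimony.tsv"), sep="\t").to_string(index=False))


if __name__ == "__main__":
    main()
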