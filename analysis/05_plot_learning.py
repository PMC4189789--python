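"""Publication-style summary figure of the simulated learning experiment.

Plots percent successful crossings versus gap distance for each genotype,
early block (sessions 1-6) versus late block (sessions 7-12), with SEM error
bars, plus per-class improvement bars.  Written to scratch/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from barrelcross import stats as st
from barrelcross.io import read_trials_csv

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "figures"
COLORS = {"WT": "black", "KO": "tab:blue"}


def main() -> None:
    trials = read_trials_csv(ROOT / "results" / "trials.csv")
    summary = st.block_rates(st.build_success_table(trials))
    rates = summary.rates
    b1, b2 = summary.blocks

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for genotype in ("WT", "KO"):
        for block, style in ((b1, "--"), (b2, "-")):
            sub = rates[(rates.genotype == genotype) & (rates.block == block)]
            g = sub.groupby("distance_cm").rate
            mean, sem = g.mean(), g.sem()
            ax1.errorbar(mean.index, mean, yerr=sem, ls=style,
                         color=COLORS[genotype], marker="o", ms=3, capsize=2,
                         label=f"{genotype} {'s1-6' if block == b1 else 's7-12'}")
    ax1.set_xlabel("gap distance (cm)")
    ax1.set_ylabel("successful crossings (%)")
    ax1.set_ylim(0, 100)
    ax1.legend(fontsize=7)

    imp = summary.improvements
    x = np.arange(2)
    width = 0.35
    for i, genotype in enumerate(("WT", "KO")):
        means = [imp[(imp.genotype == genotype) & (imp.class_label == c)].improvement.mean()
                 for c in ("nose", "whisker")]
        sems = [imp[(imp.genotype == genotype) & (imp.class_label == c)].improvement.sem()
                for c in ("nose", "whisker")]
        ax2.bar(x + (i - 0.5) * width, means, width, yerr=sems, capsize=3,
                color=COLORS[genotype], label=genotype)
    ax2.set_xticks(x, ["nose\n(3.0-4.5 cm)", "whisker\n(5.0-6.0 cm)"])
    ax2.set_ylabel("improvement (percentage points)")
    ax2.axhline(0, color="gray", lw=0.5)
    ax2.legend()

    fig.tight_layout()
    OUT.mkdir(parents=True, exist_ok=True)
    out = OUT / "learning_summary.png"
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
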