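"""Score tactile learning from the simulated trial log.

Aggregates results/trials.csv into session-block success rates (sessions 1-6
vs 7-12) by distance, runs the block x distance repeated-measures ANOVA
within each genotype and distance class, the between-genotype whisker
improvement t test, and the cohort totals control.  Writes tidy tables and a
JSON of test statistics under results/.
"""

import json
from pathlib import Path

from barrelcross import stats as st
from barrelcross.io import read_trials_csv

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    trials = read_trials_csv(RESULTS / "trials.csv")
    table = st.build_success_table(trials)
    summary = st.block_rates(table)
    summary.rates.to_csv(RESULTS / "block_rates.csv", index=False)
    summary.improvements.to_csv(RESULTS / "improvements.csv", index=False)

    stats_out = {}
    print("block x distance repeated-measures ANOVA (block main effect):")
    for genotype in ("WT", "KO"):
        for label in ("nose", "whisker"):
            res = st.rm_anova_block_by_distance(summary, genotype, label)
            stats_out[f"{genotype}_{label}"] = {
                "F": res.F, "df": [res.df1, res.df2], "p": res.p,
                "n_mice": res.n_mice, "n_distances": res.n_distances,
            }
            sig = "significant" if res.p < 0.05 else "not significant"
            print(f"  {genotype} {label:7s}: F({res.df1},{res.df2}) = {res.F:7.3f}, "
                  f"p = {res.p:.4f}  ({sig})")

    for label in ("nose", "whisker"):
        tt = st.compare_improvement(summary, label)
        stats_out[f"improvement_{label}"] = {
            "t": tt.t, "df": tt.df, "p": tt.p,
            "mean_difference_points": tt.mean_difference, "n": list(tt.n),
        }
        print(f"WT vs KO {label} improvement: t({tt.df}) = {tt.t:.3f}, p = {tt.p:.4f}, "
              f"WT - KO = {tt.mean_difference:+.1f} points")

    totals = st.cohort_totals(table)
    totals.to_csv(RESULTS / "cohort_totals.csv")
    for g in ("WT", "KO"):
        print(f"{g}: {totals.loc[g, 'mean_successes_per_mouse']:.0f} +/- "
              f"{totals.loc[g, 'sem_successes']:.0f} successes per mouse, "
              f"{totals.loc[g, 'mean_trials_per_mouse']:.0f} +/- "
              f"{totals.loc[g, 'sem_trials']:.0f} trials")

    (RESULTS / "learning_stats.json").write_text(json.dumps(stats_out, indent=2))
    print(f"wrote statistics to {RESULTS / 'learning_stats.json'}")


if __name__ == "__main__":
    main()
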