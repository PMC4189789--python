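"""Success-rate tables and learning statistics for gap-cross experiments.

Trial logs are aggregated into per-(mouse, session, distance) success counts,
collapsed into two session blocks (sessions 1-6 versus 7-12) and two distance
classes (nose: 3.0-4.5 cm, whisker: 5.0-6.0 cm), and tested with the designs
used for this assay: a two-way repeated-measures ANOVA (block x distance,
mouse as subject) within each genotype and class, and a two-sample two-tailed
t test on per-mouse improvement (block-2 minus block-1 percentage points)
between genotypes.

The block main effect is tested against the pooled within-subject error
(block x subject plus block x distance x subject), giving error df
``(n_mice - 1) * n_distances`` — the convention matching published F ratios
for this assay, e.g. F(1, 15) for six mice over three distances.  The
conventional unpooled test (block x subject error, df ``n_mice - 1``) is
returned alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_BLOCKS: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("sessions_1_6", (1, 2, 3, 4, 5, 6)),
    ("sessions_7_12", (7, 8, 9, 10, 11, 12)),
)

#: distances analysed (the assay offers up to 7.0 cm; analysis stops at 6.0)
ANALYZED_DISTANCES: tuple[float, ...] = (3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)


def distance_classes(nose_includes_4p5: bool = True) -> dict[str, tuple[float, ...]]:
    """Nose vs whisker distance classes over the analysed 3.0-6.0 cm range.

    4.5 cm sits on the boundary between snout reach and whisker-only reach;
    by default it is assigned to the nose class so the classes exhaust the
    analysed range, with ``nose_includes_4p5=False`` dropping it.
    """
    nose = (3.0, 3.5, 4.0, 4.5) if nose_includes_4p5 else (3.0, 3.5, 4.0)
    return {"nose": nose, "whisker": (5.0, 5.5, 6.0)}


REQUIRED_LOG_COLUMNS = ("mouse_id", "genotype", "session", "trial_index", "distance_cm", "outcome")

TABLE_COLUMNS = ("mouse_id", "genotype", "session", "distance_cm", "n_trials", "n_success")


def build_success_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a trial log into per-(mouse, session, distance) counts.

    Counts partition the log exactly: per-mouse totals equal the raw row
    counts.  Duplicate (mouse, session, trial_index) rows indicate a corrupt
    log and are rejected.
    """
    missing = [c for c in REQUIRED_LOG_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial log is missing columns {missing}")
    if trials.empty:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    dup = trials.duplicated(subset=["mouse_id", "session", "trial_index"])
    if dup.any():
        rows = trials.loc[dup, ["mouse_id", "session", "trial_index"]].head()
        raise ValueError(f"duplicate (mouse, session, trial_index) rows, e.g.\n{rows}")
    bad = set(trials["outcome"].unique()) - {"success", "failure"}
    if bad:
        raise ValueError(f"unknown outcome labels {sorted(bad)}")
    work = trials.copy()
    work["_success"] = (work["outcome"] == "success").astype(int)
    table = (
        work.groupby(["mouse_id", "genotype", "session", "distance_cm"], as_index=False)
        .agg(n_trials=("outcome", "size"), n_success=("_success", "sum"))
    )
    return table[list(TABLE_COLUMNS)]


@dataclass
class BlockSummary:
    """Per-(mouse, distance, block) rates and per-(mouse, class) improvements."""

    rates: pd.DataFrame  # mouse_id, genotype, distance_cm, block, n_trials, n_success, rate
    improvements: pd.DataFrame  # mouse_id, genotype, class_label, improvement, n_distances
    blocks: tuple[str, str]
    classes: dict[str, tuple[float, ...]]


def block_rates(
    table: pd.DataFrame,
    blocks: Sequence[tuple[str, Sequence[int]]] = DEFAULT_BLOCKS,
    classes: Optional[Mapping[str, Sequence[float]]] = None,
    pool: str = "pooled",
) -> BlockSummary:
    """Collapse a success table into block rates and per-class improvements.

    Rates are percentages.  ``pool="pooled"`` (default) computes
    ``100 * sum(successes) / sum(trials)`` over the block's sessions — robust
    to sessions with few trials at a distance under the adaptive rule —
    while ``pool="per_session"`` averages per-session percentages instead.
    A (mouse, distance, block) cell with no trials is missing: it is excluded
    from that mouse's class improvement and logged.  Improvement is the
    block-2 minus block-1 rate averaged over the class distances that have
    data in both blocks.
    """
    if table.empty:
        raise ValueError("empty success table")
    if pool not in ("pooled", "per_session"):
        raise ValueError(f"unknown pool mode {pool!r}")
    blocks = tuple((name, tuple(sess)) for name, sess in blocks)
    if len(blocks) != 2:
        raise ValueError("exactly two session blocks are required")
    covered = [s for _, sess in blocks for s in sess]
    if len(set(covered)) != len(covered):
        raise ValueError("session blocks overlap")
    if classes is None:
        classes = distance_classes()
    classes = {k: tuple(v) for k, v in classes.items()}
    class_dists = [d for ds in classes.values() for d in ds]
    if len(set(class_dists)) != len(class_dists):
        raise ValueError("distance classes overlap")

    session_block = {s: name for name, sess in blocks for s in sess}
    work = table[table["distance_cm"].isin(class_dists)].copy()
    work["block"] = work["session"].map(session_block)
    work = work.dropna(subset=["block"])
    if work.empty:
        raise ValueError("no trials at analysed distances within the session blocks")

    if pool == "pooled":
        rates = (
            work.groupby(["mouse_id", "genotype", "distance_cm", "block"], as_index=False)
            .agg(n_trials=("n_trials", "sum"), n_success=("n_success", "sum"))
        )
        rates["rate"] = 100.0 * rates["n_success"] / rates["n_trials"]
    else:
        work = work.assign(session_rate=100.0 * work["n_success"] / work["n_trials"])
        rates = (
            work.groupby(["mouse_id", "genotype", "distance_cm", "block"], as_index=False)
            .agg(n_trials=("n_trials", "sum"), n_success=("n_success", "sum"),
                 rate=("session_rate", "mean"))
        )

    b1, b2 = blocks[0][0], blocks[1][0]
    wide = rates.pivot_table(index=["mouse_id", "genotype", "distance_cm"],
                             columns="block", values="rate", aggfunc="first")
    imp_rows = []
    for (mouse, genotype), sub in wide.groupby(["mouse_id", "genotype"]):
        dist_idx = sub.index.get_level_values("distance_cm")
        for label, dists in classes.items():
            cols = [c for c in (b1, b2) if c in sub.columns]
            in_class = sub.loc[dist_idx.isin(dists)]
            both = (
                in_class.dropna(subset=cols)
                if len(cols) == 2
                else in_class.iloc[0:0]
            )
            n_missing = len(dists) - len(both)
            if n_missing:
                logger.warning(
                    "mouse %s: %d %s-class distance(s) missing a block, excluded",
                    mouse, n_missing, label,
                )
            imp = float((both[b2] - both[b1]).mean()) if len(both) else float("nan")
            imp_rows.append(
                {"mouse_id": mouse, "genotype": genotype, "class_label": label,
                 "improvement": imp, "n_distances": len(both)}
            )
    improvements = pd.DataFrame(imp_rows)
    return BlockSummary(rates=rates, improvements=improvements,
                        blocks=(b1, b2), classes=classes)


@dataclass(frozen=True)
class RmAnovaResult:
    """Block main effect of a block x distance repeated-measures ANOVA."""

    F: float
    df1: int
    df2: int
    p: float
    n_mice: int
    n_distances: int
    ss_block: float
    ss_error: float
    #: conventional unpooled test (block x subject error, df n_mice - 1)
    F_unpooled: float
    df2_unpooled: int
    p_unpooled: float


def _f_p(ss_num: float, df1: int, ss_den: float, df2: int) -> tuple[float, float]:
    if ss_den <= 1e-12 * max(1.0, abs(ss_num)):
        if ss_num <= 1e-12:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_num / df1) / (ss_den / df2)
    return F, float(sps.f.sf(F, df1, df2))


def rm_anova_block_by_distance(
    summary: BlockSummary, genotype: str, class_label: str
) -> RmAnovaResult:
    """Block x distance repeated-measures ANOVA within one genotype and class.

    Per-mouse percentage success rates at each (distance, block) cell enter a
    two-way within-subject design.  Distances for which any mouse is missing
    a block cell are dropped listwise (with a warning); the test then refuses
    if fewer than two mice or two distances remain.
    """
    if class_label not in summary.classes:
        raise ValueError(f"unknown distance class {class_label!r}")
    dists = summary.classes[class_label]
    b1, b2 = summary.blocks
    sub = summary.rates[
        (summary.rates["genotype"] == genotype)
        & (summary.rates["distance_cm"].isin(dists))
    ]
    if sub.empty:
        raise ValueError(f"no data for genotype {genotype!r} in class {class_label!r}")
    cube = sub.pivot_table(index="mouse_id", columns=["distance_cm", "block"],
                           values="rate", aggfunc="first")
    mice = list(cube.index)
    kept = []
    for d in dists:
        cols = [(d, b1), (d, b2)]
        if all(c in cube.columns for c in cols) and cube[cols].notna().all().all():
            kept.append(d)
        else:
            logger.warning("distance %.1f cm dropped listwise for %s/%s (missing cells)",
                           d, genotype, class_label)
    if len(mice) < 2 or len(kept) < 2:
        raise ValueError(
            f"need >= 2 mice and >= 2 complete distances for {genotype}/{class_label}; "
            f"have {len(mice)} mice, complete distances {kept}"
        )
    n, k = len(mice), len(kept)
    Y = np.empty((n, k, 2))
    for j, d in enumerate(kept):
        Y[:, j, 0] = cube[(d, b1)].to_numpy()
        Y[:, j, 1] = cube[(d, b2)].to_numpy()

    mu = Y.mean()
    m_b = Y.mean(axis=(0, 1))  # block means
    m_s = Y.mean(axis=(1, 2))  # subject means
    m_d = Y.mean(axis=(0, 2))  # distance means
    m_sb = Y.mean(axis=1)  # subject x block
    m_sd = Y.mean(axis=2)  # subject x distance
    m_db = Y.mean(axis=0)  # distance x block

    ss_block = n * k * float(((m_b - mu) ** 2).sum())
    ss_bs = k * float(
        ((m_sb - m_s[:, None] - m_b[None, :] + mu) ** 2).sum()
    )
    resid = (
        Y
        - m_sd[:, :, None]
        - m_sb[:, None, :]
        - m_db[None, :, :]
        + m_s[:, None, None]
        + m_d[None, :, None]
        + m_b[None, None, :]
        - mu
    )
    ss_bds = float((resid**2).sum())

    df2 = (n - 1) * k
    F, p = _f_p(ss_block, 1, ss_bs + ss_bds, df2)
    F_u, p_u = _f_p(ss_block, 1, ss_bs, n - 1)
    return RmAnovaResult(
        F=F, df1=1, df2=df2, p=p, n_mice=n, n_distances=k,
        ss_block=ss_block, ss_error=ss_bs + ss_bds,
        F_unpooled=F_u, df2_unpooled=n - 1, p_unpooled=p_u,
    )


@dataclass(frozen=True)
class ImprovementTest:
    """Two-sample two-tailed t test on per-mouse class improvements."""

    t: float
    df: int
    p: float
    mean_difference: float  # first genotype minus second, percentage points
    n: tuple[int, int]


def compare_improvement(
    summary: BlockSummary, class_label: str, genotypes: tuple[str, str] = ("WT", "KO")
) -> ImprovementTest:
    """Compare per-mouse improvement between genotypes (Student's t, two-tailed)."""
    if class_label not in summary.classes:
        raise ValueError(f"unknown distance class {class_label!r}")
    imp = summary.improvements
    groups = []
    for g in genotypes:
        v = imp.loc[
            (imp["genotype"] == g) & (imp["class_label"] == class_label), "improvement"
        ].dropna().to_numpy()
        if len(v) < 2:
            raise ValueError(f"genotype {g!r} has fewer than 2 mice with {class_label} data")
        groups.append(v)
    a, b = groups
    df = len(a) + len(b) - 2
    mean_diff = float(a.mean() - b.mean())
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if mean_diff == 0:
            return ImprovementTest(t=0.0, df=df, p=1.0, mean_difference=0.0, n=(len(a), len(b)))
        t = float("inf") if mean_diff > 0 else float("-inf")
        return ImprovementTest(t=t, df=df, p=0.0, mean_difference=mean_diff, n=(len(a), len(b)))
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return ImprovementTest(t=float(t), df=df, p=float(p),
                           mean_difference=mean_diff, n=(len(a), len(b)))


def cohort_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype trial and success totals with per-mouse mean +/- SEM.

    Used as the mobility/motivation control: genotypes that differ in
    learning but not in how much they run the task should show similar
    totals.  SEM is NaN for a single-mouse genotype.
    """
    if table.empty:
        raise ValueError("empty success table")
    per_mouse = (
        table.groupby(["genotype", "mouse_id"], as_index=False)
        .agg(trials=("n_trials", "sum"), successes=("n_success", "sum"))
    )

    def sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    out = per_mouse.groupby("genotype").agg(
        n_mice=("mouse_id", "size"),
        total_trials=("trials", "sum"),
        total_successes=("successes", "sum"),
        mean_trials_per_mouse=("trials", "mean"),
        sem_trials=("trials", sem),
        mean_successes_per_mouse=("successes", "mean"),
        sem_successes=("successes", sem),
    )
    return out
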