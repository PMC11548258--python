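"""Four-criterion relevance screening of oculomotor characteristics.

The screening compiles, per characteristic, the machine twin of the method's
correlation table:

1. **Landolt rings** — sessions are split into high/low mental performance
   at the Au threshold (1.5 by default: Au >= 1.5 is high) and the two
   groups are compared with the two-sided Wilcoxon rank-sum test.
2. **Inner-session dynamics** — the proportion of sessions in which the
   characteristic increased from the beginning to the end of the session,
   the proportion in which it decreased, and the larger of the two.
3. **CRT** — for every fixation-area diameter on a grid, the correlation of
   the characteristic with the within-session reaction-time delta (post
   minus pre mean RT); the signed correlation of largest magnitude and its
   argmax diameter are kept.
4. **VAS-F** — the same max-over-diameters correlation against the
   pre-session fatigue score.

The final step filters at raw p < alpha (no multiplicity correction — the
screening is deliberately liberal; a Benjamini-Hochberg option exists),
ranks by p, then dynamics score, then |CRT correlation|, and unions the
ranked head with explicit expert additions.  Selection size and additions
are configuration, because the expert step is judgment, not computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .characteristics import (
    CATALOGUE_KEYS,
    EXPERT_ADDITIONS,
    LABELS,
    recording_characteristics,
)
from .events import EventConfig
from .recording import GazeDataError, InvalidParameterError
from .study import StudyDataset

AU_THRESHOLD_DEFAULT = 1.5

#: Fixation-area diameters scanned for the CRT/VAS-F correlations (deg).
DEFAULT_DIAMETER_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.1, 2.51, 0.1), 1)
)


def label_by_mental_performance(
    au: float | None, threshold: float = AU_THRESHOLD_DEFAULT
) -> str | None:
    """Dichotomise the Landolt Au index: 'high' iff au >= threshold.

    An absent Au gives None; such sessions are excluded downstream.
    """
    if au is None or not np.isfinite(au):
        return None
    return "high" if au >= threshold else "low"


def wilcoxon_rank_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for two groups.

    Uses the exact null distribution for combined n <= 25 without ties and
    the tie-corrected normal approximation otherwise.  All-tied pooled
    values give p = 1 (no evidence of a shift whatsoever).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def landolt_wilcoxon(
    matrix: pd.DataFrame, labels: pd.Series | np.ndarray
) -> pd.Series:
    """Per-characteristic Wilcoxon p comparing high vs low performance rows.

    ``matrix`` has one row per session and one column per characteristic;
    ``labels`` holds 'high'/'low' (None rows are dropped).
    """
    labels = pd.Series(list(labels), index=matrix.index)
    keep = labels.isin(["high", "low"])
    matrix, labels = matrix[keep], labels[keep]
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise InvalidParameterError("need at least one session in each Au group")
    out = {}
    for col in matrix.columns:
        hi = matrix.loc[labels == "high", col].to_numpy(dtype=float)
        lo = matrix.loc[labels == "low", col].to_numpy(dtype=float)
        hi, lo = hi[np.isfinite(hi)], lo[np.isfinite(lo)]
        out[col] = wilcoxon_rank_p(hi, lo) if hi.size and lo.size else np.nan
    return pd.Series(out, name="wilcoxon_p")


def session_characteristic_matrix(
    study: StudyDataset, cfg: EventConfig | None = None
) -> pd.DataFrame:
    """One row per session, one column per catalogue characteristic."""
    cfg = cfg or EventConfig()
    rows = {
        s.key: recording_characteristics(s.recording, cfg).as_series() for s in study
    }
    df = pd.DataFrame(rows).T
    df.index = pd.MultiIndex.from_tuples(df.index, names=["participant_id", "session_id"])
    return df


def session_block_matrices(
    study: StudyDataset,
    cfg: EventConfig | None = None,
    block_fraction: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Characteristics on the first and last blocks of each session.

    The blocks stand in for the reaction-time task epochs that open and
    close a session: the first and last ``block_fraction`` of the recording.
    """
    if not 0 < block_fraction <= 0.5:
        raise InvalidParameterError("block_fraction must be in (0, 0.5]")
    cfg = cfg or EventConfig()
    first, last = {}, {}
    for s in study:
        rec = s.recording
        if len(rec) < 4:
            warnings.warn(f"session {s.key} too short for dynamics; skipped")
            continue
        t0, dur = float(rec.t[0]), rec.duration
        first[s.key] = recording_characteristics(
            rec.time_slice(t0, t0 + dur * block_fraction), cfg
        ).as_series()
        last[s.key] = recording_characteristics(
            rec.time_slice(t0 + dur * (1 - block_fraction), t0 + dur + 1e-9), cfg
        ).as_series()
    return pd.DataFrame(first).T, pd.DataFrame(last).T


def inner_session_dynamics(
    start_values: pd.Series | np.ndarray, end_values: pd.Series | np.ndarray
) -> tuple[float, float, float]:
    """Proportions of sessions where a characteristic rose / fell.

    Returns ``(up, down, score)`` with ``score = max(up, down)``; sessions
    where the two block values are equal (or either is absent) count in
    neither proportion, but stay in the denominator.
    """
    a = np.asarray(start_values, dtype=float)
    b = np.asarray(end_values, dtype=float)
    if a.size != b.size or a.size == 0:
        raise InvalidParameterError("need paired, non-empty block values")
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n == 0:
        return (0.0, 0.0, 0.0)
    up = float((b[ok] > a[ok]).sum()) / n
    down = float((b[ok] < a[ok]).sum()) / n
    return (up, down, max(up, down))


def max_abs_correlation_over_diameters(
    per_diameter_values: dict[float, np.ndarray],
    target: np.ndarray,
    method: str = "spearman",
) -> tuple[float, float] | None:
    """Signed correlation of maximal magnitude across fixation-area diameters.

    ``per_diameter_values`` maps each diameter to the session-level values
    of one characteristic recomputed at that diameter; ``target`` holds the
    paired session-level criterion (CRT delta or VAS-F fatigue).  Diameters
    where the characteristic is constant or has < 3 finite pairs are
    skipped; if every diameter is skipped the result is None.
    """
    if method not in ("spearman", "pearson"):
        raise InvalidParameterError(f"unknown correlation method {method!r}")
    target = np.asarray(target, dtype=float)
    best: tuple[float, float] | None = None
    for diam in sorted(per_diameter_values):
        vals = np.asarray(per_diameter_values[diam], dtype=float)
        if vals.shape != target.shape:
            raise InvalidParameterError("characteristic/target length mismatch")
        ok = np.isfinite(vals) & np.isfinite(target)
        if ok.sum() < 3 or np.all(vals[ok] == vals[ok][0]):
            continue
        if np.all(target[ok] == target[ok][0]):
            continue
        if method == "spearman":
            r = stats.spearmanr(vals[ok], target[ok]).statistic
        else:
            r = stats.pearsonr(vals[ok], target[ok]).statistic
        if np.isfinite(r) and (best is None or abs(r) > abs(best[0])):
            best = (float(r), float(diam))
    return best


@dataclass
class SelectionResult:
    """Outcome of the screening + expert selection."""

    filtered: list[str]
    ranked: list[str]
    expert_additions: list[str]
    selected: list[str]


def compile_relevance_table(
    study: StudyDataset,
    cfg: EventConfig | None = None,
    diameter_grid: tuple[float, ...] | None = DEFAULT_DIAMETER_GRID,
    au_threshold: float = AU_THRESHOLD_DEFAULT,
    block_fraction: float = 0.1,
    method: str = "spearman",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Compile all four screening criteria for every catalogue characteristic.

    Returns a frame indexed by characteristic key, sorted by Wilcoxon p
    ascending (ties keep catalogue order), with columns: label, wilcoxon_p,
    dynamics_up, dynamics_down, dynamics_score, crt_corr, crt_diameter,
    vasf_corr, vasf_diameter.  A ground-truth modality absent from the whole
    study leaves its columns NaN.  With ``bh_correction`` the p-values are
    Benjamini-Hochberg adjusted (off by default: the screening filters at
    raw p).
    """
    cfg = cfg or EventConfig()
    base = session_characteristic_matrix(study, cfg)

    aus = [s.ground_truth.au for s in study]
    labels = [label_by_mental_performance(a, au_threshold) for a in aus]
    p = landolt_wilcoxon(base, labels)
    if bh_correction:
        p = pd.Series(
            stats.false_discovery_control(p.fillna(1.0).to_numpy(), method="bh"),
            index=p.index,
            name="wilcoxon_p",
        )

    first, last = session_block_matrices(study, cfg, block_fraction)
    dyn = {
        k: inner_session_dynamics(first[k], last[k]) for k in CATALOGUE_KEYS
    }

    per_diam: dict[float, pd.DataFrame] = {}
    if diameter_grid:
        for d in diameter_grid:
            if float(d) == cfg.area_diameter:
                per_diam[float(d)] = base
            else:
                per_diam[float(d)] = session_characteristic_matrix(
                    study, cfg.with_diameter(float(d))
                )

    crt_delta = np.array(
        [np.nan if s.ground_truth.crt_delta is None else s.ground_truth.crt_delta
         for s in study]
    )
    vasf = np.array(
        [np.nan if s.ground_truth.vasf_fatigue is None else s.ground_truth.vasf_fatigue
         for s in study]
    )

    rows = []
    for key in CATALOGUE_KEYS:
        row = {
            "label": LABELS[key],
            "wilcoxon_p": p.get(key, np.nan),
            "dynamics_up": dyn[key][0],
            "dynamics_down": dyn[key][1],
            "dynamics_score": dyn[key][2],
            "crt_corr": np.nan,
            "crt_diameter": np.nan,
            "vasf_corr": np.nan,
            "vasf_diameter": np.nan,
        }
        if per_diam:
            values = {d: df[key].to_numpy(dtype=float) for d, df in per_diam.items()}
            for name, target in (("crt", crt_delta), ("vasf", vasf)):
                if np.isfinite(target).sum() >= 3:
                    best = max_abs_correlation_over_diameters(values, target, method)
                    if best is not None:
                        row[f"{name}_corr"], row[f"{name}_diameter"] = best
        rows.append(row)
    table = pd.DataFrame(rows, index=list(CATALOGUE_KEYS))
    return table.sort_values("wilcoxon_p", kind="stable")


def select_characteristics(
    table: pd.DataFrame,
    alpha: float = 0.05,
    expert_additions: tuple[str, ...] = EXPERT_ADDITIONS,
    head_size: int = 6,
) -> SelectionResult:
    """Filter at p < alpha, rank, and union the head with expert additions.

    Ranking is by Wilcoxon p ascending, then dynamics score descending,
    then |CRT correlation| descending, then catalogue order.  The selected
    set is the first ``head_size`` ranked characteristics plus the expert
    additions (deduplicated, order preserved).
    """
    for k in expert_additions:
        if k not in table.index:
            raise InvalidParameterError(f"unknown expert addition {k!r}")
    filtered = table[table["wilcoxon_p"] < alpha]
    if filtered.empty and not expert_additions:
        raise GazeDataError(
            "no characteristic passed the p filter and no expert additions were "
            "given; review alpha or the study"
        )
    order = {k: i for i, k in enumerate(CATALOGUE_KEYS)}
    ranked = sorted(
        filtered.index,
        key=lambda k: (
            filtered.loc[k, "wilcoxon_p"],
            -(filtered.loc[k, "dynamics_score"] if np.isfinite(filtered.loc[k, "dynamics_score"]) else 0.0),
            -(abs(filtered.loc[k, "crt_corr"]) if np.isfinite(filtered.loc[k, "crt_corr"]) else 0.0),
            order.get(k, len(order)),
        ),
    )
    # the head is drawn from the non-expert candidates so the final set
    # always has head_size + len(additions) members, as in the published
    # configuration (six ranked characteristics plus one expert addition)
    head = [k for k in ranked if k not in expert_additions][:head_size]
    selected = list(head)
    for k in expert_additions:
        if k not in selected:
            selected.append(k)
    return SelectionResult(
        filtered=list(filtered.index),
        ranked=ranked,
        expert_additions=list(expert_additions),
        selected=selected,
    )


def export_relevance_table(table: pd.DataFrame, path) -> None:
    """Write the relevance table as delimited text shaped like the method's
    published summary (characteristic, p, dynamics, CRT, VAS-F columns)."""
    out = table.copy()
    for col in ("dynamics_up", "dynamics_down", "dynamics_score"):
        out[col] = (100.0 * out[col]).round(2)
    for col in ("crt_corr", "vasf_corr"):
        out[col] = (100.0 * out[col]).round(2)
    out.to_csv(path, index_label="characteristic")
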