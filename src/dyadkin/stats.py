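"""Fisher transformation and 2x2 within-subject condition summaries.

Per-trial absolute-maximum correlations are variance-stabilized with the
Fisher transformation Z = (1/2) ln((1+r)/(1-r)) before averaging across
trials (a config switch restores average-then-transform).  Condition
means feed within-subject 2x2 factorial tests: univariate F tests per
dependent variable (df (1, n-1)) and a multivariate Hotelling T^2 test
across a DV triple (reported as an exact F with df (p, n-p)); for 2-level
factors every multivariate criterion (Pillai, Wilks, Hotelling-Lawley)
yields this same F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CONDITIONS, CrossedCondition, Difficulty, Feedback
from .kinematics import DV_NAMES

EFFECTS = ("feedback", "difficulty", "interaction")

#: DV families mirroring the reported analyses.
DV_SETS = {
    "joint_angle": ("q1", "q2", "q3"),
    "grip_position": ("grip_x", "grip_y", "grip_z"),
    "grip_aperture": ("aperture",),
}

_R_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Z = (1/2) ln((1+r)/(1-r)); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| >= 1 has infinite Z; clip or exclude first")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    """r = tanh(Z), the inverse Fisher transformation."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def build_condition_table(
    trial_results: pd.DataFrame,
    z_before_mean: bool = True,
) -> pd.DataFrame:
    """Aggregate per-trial coupling into one row per person/condition/DV.

    ``trial_results`` is tidy with columns ``person_id, feedback,
    difficulty, dv, trial, r_abs, lag_s`` (NaN rows = excluded trials).
    With ``z_before_mean`` each trial's r is Fisher-transformed before
    averaging; otherwise the trial-mean r is transformed.  r values at 1
    (possible on noiseless synthetic data) are clipped to ``1 - 1e-7``
    with a warning.  The table must cover all four crossed conditions for
    every person.
    """
    required = {"person_id", "feedback", "difficulty", "dv", "trial", "r_abs", "lag_s"}
    missing = required - set(trial_results.columns)
    if missing:
        raise ValueError(f"trial_results missing columns: {sorted(missing)}")

    df = trial_results.copy()
    n_clipped = int((df["r_abs"] >= 1.0).sum())
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} r values at 1 - 1e-7", stacklevel=2)
        df["r_abs"] = df["r_abs"].clip(upper=_R_CLIP)

    for pid, grp in df.groupby("person_id"):
        have = {(Feedback(f), Difficulty(d))
                for f, d in grp[["feedback", "difficulty"]].drop_duplicates().itertuples(index=False)}
        for cond in CONDITIONS:
            if (cond.feedback, cond.difficulty) not in have:
                raise ValueError(
                    f"person {pid} is missing condition {cond.label}"
                )

    rows = []
    for (pid, fb, dif, dv), grp in df.groupby(
        ["person_id", "feedback", "difficulty", "dv"], sort=False
    ):
        r = grp["r_abs"].dropna().to_numpy()
        lag = grp["lag_s"].dropna().to_numpy()
        if len(r) == 0:
            raise ValueError(f"no usable trials for {pid}/{fb}/{dif}/{dv}")
        if z_before_mean:
            mean_z = float(np.mean(fisher_z(r)))
        else:
            mean_z = float(fisher_z(min(np.mean(r), _R_CLIP)))
        rows.append(
            {
                "person_id": pid,
                "feedback": Feedback(fb).value,
                "difficulty": Difficulty(dif).value,
                "dv": dv,
                "mean_z": mean_z,
                "mean_r_equiv": inverse_fisher(mean_z),
                "mean_lag_s": float(np.mean(lag)),
                "n_trials": int(len(r)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TestResult:
    effect: str              # feedback | difficulty | interaction
    scope: str               # multivariate | univariate
    dv: str                  # DV name, or the DV-set name for multivariate
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float


def _contrasts(cell: np.ndarray) -> dict[str, np.ndarray]:
    """Per-person effect contrasts from an (n, 4) cell array.

    Column order: (f2f, simple), (f2f, complex), (video, simple),
    (video, complex).
    """
    f2f = cell[:, :2].mean(axis=1)
    vid = cell[:, 2:].mean(axis=1)
    simple = cell[:, [0, 2]].mean(axis=1)
    cplx = cell[:, [1, 3]].mean(axis=1)
    return {
        "feedback": f2f - vid,
        "difficulty": simple - cplx,
        "interaction": (cell[:, 0] - cell[:, 1]) - (cell[:, 2] - cell[:, 3]),
    }


def _univariate_f(c: np.ndarray) -> tuple:
    """One-sample test of a within-subject contrast: F(1, n-1) = t^2."""
    n = len(c)
    df = (1, n - 1)
    if np.allclose(c, 0.0):
        return 0.0, df, 1.0, 0.0
    sd = c.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate contrast: zero variance, nonzero mean")
    t = c.mean() / (sd / np.sqrt(n))
    F = t**2
    p = float(sps.f.sf(F, *df))
    return float(F), df, p, float(F / (F + df[1]))


def _multivariate_f(C: np.ndarray) -> tuple:
    """One-sample Hotelling T^2 on (n, p) contrast vectors -> exact F."""
    n, p = C.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than DVs ({p})")
    df = (p, n - p)
    if np.allclose(C, 0.0):
        return 0.0, df, 1.0, 0.0
    cbar = C.mean(axis=0)
    S = np.cov(C, rowvar=False, ddof=1)
    try:
        sol = np.linalg.solve(S, cbar)
    except np.linalg.LinAlgError:
        raise ValueError("singular contrast covariance; test undefined") from None
    T2 = n * float(cbar @ sol)
    F = (n - p) / (p * (n - 1)) * T2
    p_val = float(sps.f.sf(F, *df))
    return float(F), df, p_val, float(T2 / (T2 + n - 1))


def _cell_matrix(table: pd.DataFrame, dv: str, measure: str) -> np.ndarray:
    col = {"z": "mean_z", "lag": "mean_lag_s"}[measure]
    sub = table[table["dv"] == dv]
    pivot = sub.pivot_table(
        index="person_id", columns=["feedback", "difficulty"], values=col
    )
    order = [(c.feedback.value, c.difficulty.value) for c in CONDITIONS]
    try:
        pivot = pivot[order]
    except KeyError as exc:
        raise ValueError(f"unbalanced table for dv {dv}: missing cell {exc}") from None
    if pivot.isna().any().any():
        raise ValueError(f"unbalanced table for dv {dv}: NaN cells")
    return pivot.to_numpy()


def rm_2x2_test(
    table: pd.DataFrame,
    dv_set: tuple[str, ...] | list[str] | str,
    measure: str = "z",
) -> list[TestResult]:
    """Within-subject 2x2 factorial tests on condition means.

    ``table`` is the output of :func:`build_condition_table`; ``dv_set``
    is a DV tuple or one of the named families in :data:`DV_SETS`;
    ``measure`` selects the Fisher-Z or lag summary.  For multi-DV sets a
    multivariate test (df (p, n-p)) is reported alongside the univariate
    tests per DV (df (1, n-1)), for the feedback and difficulty main
    effects and their interaction.
    """
    if isinstance(dv_set, str):
        set_name, dvs = dv_set, DV_SETS[dv_set]
    else:
        dvs = tuple(dv_set)
        set_name = "+".join(dvs)
    cells = {dv: _cell_matrix(table, dv, measure) for dv in dvs}
    n = next(iter(cells.values())).shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")

    results: list[TestResult] = []
    per_dv_contrasts = {dv: _contrasts(cells[dv]) for dv in dvs}
    for effect in EFFECTS:
        if len(dvs) > 1:
            C = np.column_stack([per_dv_contrasts[dv][effect] for dv in dvs])
            F, df, p, eta = _multivariate_f(C)
            results.append(TestResult(effect, "multivariate", set_name, F, df, p, eta))
        for dv in dvs:
            F, df, p, eta = _univariate_f(per_dv_contrasts[dv][effect])
            results.append(TestResult(effect, "univariate", dv, F, df, p, eta))
    return results


def summarize_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Full test table across DV families and both measures (Z, lag)."""
    rows = []
    for measure in ("z", "lag"):
        for set_name in DV_SETS:
            for res in rm_2x2_test(table, set_name, measure):
                rows.append(
                    {
                        "measure": measure,
                        "dv_set": set_name,
                        "dv": res.dv,
                        "scope": res.scope,
                        "effect": res.effect,
                        "F": res.F,
                        "df1": res.df[0],
                        "df2": res.df[1],
                        "p": res.p,
                        "partial_eta_sq": res.partial_eta_sq,
                    }
                )
    return pd.DataFrame(rows)
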