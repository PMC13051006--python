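"""Bespoke scores of the aided face-matching design.

Contains the display transform applied to raw AFR similarity values, the
pre-registered change-in-confidence (CIC) score, the adherence-to-AFR score,
the 10-item trust-in-AI sum score, and Cronbach's alpha for that scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "transform_similarity",
    "cic",
    "pair_mean_cic",
    "adherence",
    "trust_score",
    "cronbach_alpha",
]

RAW_MIN = -0.1
RAW_MAX = 1.0
RAW_THRESHOLD = 0.3  # raw similarity above this means the AFR says "match"
DISPLAY_THRESHOLD = 0.5

_EPS = 1e-12


def transform_similarity(raw):
    """Map raw AFR similarity in [-0.1, 1] onto the 0-1 display scale.

    The AFR's decision threshold sits at a raw similarity of 0.3; for display
    the two sides of the threshold are stretched linearly so that the
    threshold lands at 0.5 and the endpoints at 0 and 1:

    * raw in [0.3, 1]   -> displayed in [0.5, 1]
    * raw in [-0.1, 0.3) -> displayed in [0, 0.5)

    Scalars or arrays; values outside [-0.1, 1] raise ``ValueError``.
    """
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < RAW_MIN - _EPS) or np.any(arr > RAW_MAX + _EPS):
        bad = arr[(arr < RAW_MIN - _EPS) | (arr > RAW_MAX + _EPS)]
        raise ValueError(
            f"raw similarity outside [{RAW_MIN}, {RAW_MAX}] "
            f"(corrupt AFR output?): {np.atleast_1d(bad)[:10].tolist()}"
        )
    arr = np.clip(arr, RAW_MIN, RAW_MAX)
    out = np.where(
        arr >= RAW_THRESHOLD,
        0.5 + 0.5 * (arr - RAW_THRESHOLD) / (RAW_MAX - RAW_THRESHOLD),
        0.5 * (arr - RAW_MIN) / (RAW_THRESHOLD - RAW_MIN),
    )
    return float(out) if np.isscalar(raw) or np.ndim(raw) == 0 else out


def _check_rating(x, name):
    arr = np.asarray(x)
    if np.any((arr < 1) | (arr > 6) | (arr != np.floor(arr))):
        raise ValueError(f"{name} ratings must be integers in 1..6")
    return arr.astype(float)


def cic(without, with_aid):
    """Change-in-confidence score, normalised by the headroom available.

    For an unaided rating *u* and aided rating *a*, both on the 1-6 scale::

        a == u -> 0
        a >  u -> (a - u) / (6 - u)    increase over the maximum increase
        a <  u -> (a - u) / (u - 1)    decrease over the maximum decrease

    so CIC lies in [-1, 1] and a given raw change counts for more when the
    rating is already near the end of the scale.  The branch conditions rule
    out zero denominators: u = 6 admits no increase and u = 1 no decrease.
    Vectorised over arrays.
    """
    u = _check_rating(without, "unaided")
    a = _check_rating(with_aid, "aided")
    delta = a - u
    with np.errstate(divide="ignore", invalid="ignore"):
        up = delta / (6.0 - u)
        down = delta / (u - 1.0)
    out = np.where(delta > 0, up, np.where(delta < 0, down, 0.0))
    return float(out) if np.ndim(out) == 0 else out


def pair_mean_cic(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-pair mean CIC over participants, with the pair's AFR similarity.

    Expects a tidy trial table holding both conditions (columns
    ``participant_id, pair_id, condition, rating, is_match, afr_displayed``).
    Each (participant, pair) must have exactly one unaided and one aided
    rating.  Returns one row per pair: ``pair_id, is_match, afr_displayed,
    mean_cic, n``.
    """
    wide = trials.pivot_table(
        index=["participant_id", "pair_id"],
        columns="condition",
        values="rating",
        aggfunc="first",
    )
    for col in ("unaided", "aided"):
        if col not in wide.columns:
            raise ValueError(f"trial table has no '{col}' condition rows")
    counts = trials.groupby(["participant_id", "pair_id"]).size()
    if (counts != 2).any() or wide.isna().any().any():
        raise ValueError(
            "each (participant, pair) needs exactly one unaided and one aided rating"
        )
    wide = wide.reset_index()
    wide["cic"] = cic(wide["unaided"].to_numpy(), wide["aided"].to_numpy())
    meta = trials.drop_duplicates("pair_id")[
        ["pair_id", "is_match", "afr_displayed"]
    ].set_index("pair_id")
    meta["is_match"] = meta["is_match"].astype(bool)
    agg = wide.groupby("pair_id")["cic"].agg(["mean", "size"])
    out = meta.join(agg).reset_index()
    return out.rename(columns={"mean": "mean_cic", "size": "n"})


def adherence(acc_aided: float, acc_unaided: float) -> float:
    """Fraction of the possible accuracy improvement realised when aided.

    ``(acc_aided - acc_unaided) / (1 - acc_unaided)``.  Equals 1 when the
    aid lifts the participant to perfect accuracy and can be negative when
    aided accuracy is worse.  A participant already perfect unaided has no
    headroom: the score is 0 if they stay perfect and ``nan`` (undefined,
    0/0-like) otherwise.
    """
    for name, v in (("acc_aided", acc_aided), ("acc_unaided", acc_unaided)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if acc_unaided == 1.0:
        return 0.0 if acc_aided == 1.0 else float("nan")
    return (acc_aided - acc_unaided) / (1.0 - acc_unaided)


def trust_score(items, reverse_coded=()) -> int:
    """Sum of 10 trust-in-AI items, each rated 1-5.

    ``reverse_coded`` lists 0-based indices of items to reverse
    (response -> 6 - response) before summing.  The result lies in [10, 50].
    """
    arr = np.asarray(items)
    if arr.shape != (10,):
        raise ValueError(f"expected 10 items, got shape {arr.shape}")
    if np.any((arr < 1) | (arr > 5) | (arr != np.floor(arr))):
        raise ValueError("trust items must be integers in 1..5")
    arr = arr.astype(int).copy()
    idx = list(reverse_coded)
    if idx:
        arr[idx] = 6 - arr[idx]
    return int(arr.sum())


def cronbach_alpha(items) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    ``items`` is a participants x k matrix of item responses.  Uses sample
    variances (denominator n-1):  alpha = k/(k-1) * (1 - sum(item variances)
    / variance(total score)).  Returns ``nan`` when the total score has zero
    variance.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 participants and >=2 items")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_var / total_var))
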