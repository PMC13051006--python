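"""Equal-variance signal detection measures for 6-point face-matching ratings.

Ratings 1-3 count as a "different" (mismatch) decision, 4-6 as a "same"
(match) decision.  A *hit* is a "same" response to a genuine match pair and a
*false alarm* is a "same" response to a mismatch pair; under this convention a
negative criterion C means a liberal bias toward responding "match".

Hit and false-alarm rates of exactly 0 or 1 are pulled off the boundary with
the standard 1/(2n) correction (0 -> 0.5/n, 1 -> (n-0.5)/n) before the
z-transform, where n is the number of trials of that pair type for that
participant and condition.  Overall accuracy always uses uncorrected counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "SDTMeasures",
    "rating_to_decision",
    "corrected_rate",
    "sdt_measures",
    "overall_accuracy",
    "quarter_criteria",
    "sdt_table",
]


@dataclass(frozen=True)
class SDTMeasures:
    """Hit/false-alarm rates with the derived sensitivity and bias.

    Attributes
    ----------
    hit_rate, fa_rate
        Proportions of "same" responses on match and mismatch trials, after
        the extreme-rate correction.
    d_prime
        z(H) - z(F), discriminability independent of bias.
    criterion
        C = -(z(H) + z(F)) / 2; negative values indicate a bias toward
        responding "same".
    n_match, n_mismatch
        Trial counts entering each rate.
    hit_corrected, fa_corrected
        True where the corresponding raw rate was 0 or 1 and was replaced.
    """

    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float
    n_match: int
    n_mismatch: int
    hit_corrected: bool
    fa_corrected: bool


def rating_to_decision(rating):
    """Convert 1-6 ratings to binary match decisions.

    Ratings 1-3 map to ``False`` (mismatch/different decision) and 4-6 to
    ``True`` (match/same decision).  Accepts scalars or arrays; raises
    ``ValueError`` naming the offending positions for anything outside 1..6.
    """
    arr = np.asarray(rating)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"ratings must be numeric, got dtype {arr.dtype}")
    bad = (arr < 1) | (arr > 6) | (arr != np.floor(arr)) | ~np.isfinite(arr)
    if np.any(bad):
        idx = np.argwhere(np.atleast_1d(bad)).ravel()[:10].tolist()
        raise ValueError(
            f"ratings must be integers in 1..6; invalid values at rows {idx}: "
            f"{np.atleast_1d(arr)[np.atleast_1d(bad)][:10].tolist()}"
        )
    out = arr >= 4
    return bool(out) if np.isscalar(rating) or arr.ndim == 0 else out


def corrected_rate(k: int, n: int) -> float:
    """Proportion k/n with extreme values pulled off 0 and 1.

    k = 0 returns 0.5/n and k = n returns (n - 0.5)/n, so that the
    z-transform is finite.  n must be at least 1.
    """
    if n < 1:
        raise ValueError("corrected_rate needs at least one trial (n >= 1)")
    if not 0 <= k <= n:
        raise ValueError(f"count k={k} outside 0..n={n}")
    if k == 0:
        return 0.5 / n
    if k == n:
        return (n - 0.5) / n
    return k / n


def sdt_measures(ratings, is_match, *, label: str | None = None) -> SDTMeasures:
    """Compute corrected H, F, d' and criterion C from one observer's trials.

    Parameters
    ----------
    ratings
        1-6 integer ratings for one participant and condition.
    is_match
        Boolean array, True where the pair is a genuine match.
    label
        Optional identifier (e.g. participant id) used in error messages.

    Both a match and a mismatch trial must be present, otherwise one of the
    two rates is undefined.
    """
    same = np.asarray(rating_to_decision(ratings))
    match = np.asarray(is_match, dtype=bool)
    if same.shape != match.shape:
        raise ValueError("ratings and is_match must have the same length")
    n_match = int(match.sum())
    n_mismatch = int((~match).sum())
    who = f" for {label}" if label else ""
    if n_match == 0 or n_mismatch == 0:
        raise ValueError(
            f"need at least one match and one mismatch trial{who} "
            f"(got {n_match} match, {n_mismatch} mismatch)"
        )
    k_hit = int(same[match].sum())
    k_fa = int(same[~match].sum())
    hit = corrected_rate(k_hit, n_match)
    fa = corrected_rate(k_fa, n_mismatch)
    z_h = ndtri(hit)
    z_f = ndtri(fa)
    return SDTMeasures(
        hit_rate=hit,
        fa_rate=fa,
        d_prime=z_h - z_f,
        criterion=-(z_h + z_f) / 2.0,
        n_match=n_match,
        n_mismatch=n_mismatch,
        hit_corrected=k_hit in (0, n_match),
        fa_corrected=k_fa in (0, n_mismatch),
    )


def overall_accuracy(ratings, is_match) -> float:
    """Proportion of correct decisions (uncorrected counts)."""
    same = np.asarray(rating_to_decision(ratings))
    match = np.asarray(is_match, dtype=bool)
    if same.shape != match.shape:
        raise ValueError("ratings and is_match must have the same length")
    if same.size == 0:
        raise ValueError("no trials supplied")
    return float((same == match).mean())


def quarter_criteria(
    ratings,
    is_match,
    presentation_index,
    n_quarters: int = 4,
    *,
    allow_partial: bool = False,
) -> list[float]:
    """Criterion C in successive blocks of the presentation order.

    Trials are sorted by ``presentation_index`` and split into
    ``n_quarters`` contiguous blocks (40 trials each in the 160-pair
    design).  Because trial order is randomized per participant, a block may
    contain no mismatch (or no match) trials; such blocks yield ``nan``
    rather than an error, and cohort averages should be taken over the
    defined values.

    If the trial count does not divide evenly, an error is raised unless
    ``allow_partial`` is set, in which case the final block is shorter.
    """
    ratings = np.asarray(ratings)
    match = np.asarray(is_match, dtype=bool)
    order = np.argsort(np.asarray(presentation_index), kind="stable")
    ratings, match = ratings[order], match[order]
    n = ratings.size
    if n_quarters < 1:
        raise ValueError("n_quarters must be >= 1")
    if n % n_quarters != 0 and not allow_partial:
        raise ValueError(
            f"{n} trials not divisible into {n_quarters} equal blocks; "
            "pass allow_partial=True to keep a short final block"
        )
    block = int(np.ceil(n / n_quarters))
    out: list[float] = []
    for q in range(n_quarters):
        sl = slice(q * block, min((q + 1) * block, n))
        m = match[sl]
        if m.size == 0 or m.all() or not m.any():
            out.append(float("nan"))
            continue
        out.append(sdt_measures(ratings[sl], m).criterion)
    return out


def sdt_table(
    trials: pd.DataFrame,
    by=("participant_id", "condition"),
) -> pd.DataFrame:
    """Per-group SDT summary of a tidy trial table.

    Expects columns ``rating`` and ``is_match`` plus the grouping columns.
    Returns one row per group with rates, d', C and overall accuracy.
    """
    rows = []
    for keys, grp in trials.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        m = sdt_measures(
            grp["rating"].to_numpy(),
            grp["is_match"].to_numpy(dtype=bool),
            label="/".join(map(str, keys)),
        )
        rows.append(
            dict(zip(by, keys))
            | {
                "hit_rate": m.hit_rate,
                "fa_rate": m.fa_rate,
                "d_prime": m.d_prime,
                "criterion": m.criterion,
                "accuracy": overall_accuracy(
                    grp["rating"].to_numpy(), grp["is_match"].to_numpy(dtype=bool)
                ),
                "n_match": m.n_match,
                "n_mismatch": m.n_mismatch,
            }
        )
    return pd.DataFrame(rows)
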