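"""Seeded simulator of AFR-aided face-matching experiments.

Generates the full structure of a low-prevalence one-to-one face matching
study: a fixed face set (160 pairs, 10% mismatches by default) scored by a
perfectly accurate AFR whose raw similarity straddles the 0.3 decision
threshold, and cohorts of simulated observers who rate every pair twice —
first unaided, then with the AFR's output.

The observer is an equal-variance signal-detection model.  Each pair carries
a latent evidence mean ``theta`` (centred on ``d_true`` for matches, 0 for
mismatches, with pair-to-pair spread ``tau_pair``); on each trial the
observer samples evidence ``theta + N(0, obs_noise_sd)`` and reads a 1-6
rating off five ascending cutpoints.  Exposure to a 9:1 match/mismatch world
drives a liberal criterion drift: the cutpoints decay toward lower values as
a saturating exponential in presentation order, fast and deep when the AFR
gives only a binary decision, slow and shallow when a graded similarity
score reveals the system's uncertainty.  Aided ratings are produced from the
unaided rating plus an information-dependent confidence shift, so the
change-in-confidence score has a well-defined generative meaning.

All randomness flows from a single integer seed; identical seeds give
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import norm

from .scores import transform_similarity

__all__ = [
    "AfrLink",
    "GeneratorParams",
    "REGIMES",
    "generate_face_set",
    "drifted_cutpoints",
    "simulate_unaided_rating",
    "simulate_aided_rating",
    "simulate_experiment",
    "analytic_dprime",
]

REGIMES = ("graded", "binary", "none")

_EXPERIMENT_LABEL = {"graded": "exp1a", "binary": "exp1b", "none": "exp2"}

ETHNICITY_PROPORTIONS = {
    "White": 0.54,
    "Black": 0.14,
    "Asian": 0.21,
    "Mixed-Other": 0.11,
}


@dataclass(frozen=True)
class AfrLink:
    """Constants coupling a pair's latent evidence to its AFR similarity.

    The AFR raw score is a sigmoid of ``slope * (theta + zeta)`` with
    ``zeta ~ N(0, noise_sd^2)``, squeezed into the correct side of the 0.3
    threshold.  The defaults target a human-AFR correlation of about .5 on
    match pairs: with ``tau_pair = 0.5`` the latent correlation
    ``tau / sqrt(tau^2 + noise_sd^2)`` is 0.53 and the mild sigmoid
    compression brings the realised Pearson r close to the 0.5 target.
    """

    slope: float = 0.6
    noise_sd: float = 0.8
    rho_target: float = 0.5


@dataclass(frozen=True)
class GeneratorParams:
    """All distributional constants of the synthetic experiment.

    Defaults describe the study conditions: 160 pairs with 10% mismatches, a
    100%-accurate AFR, an observer separation of ``d_true = 1.5`` latent SD
    units, and criterion drift that is fast/deep under binary AFR feedback
    (and under no feedback, where prevalence alone drives it) but slow and
    shallow under graded feedback.

    The middle rating cutpoint sits halfway between the two evidence means,
    so the starting binary criterion is near 0; the outer cutpoints are wide
    because unaided observers rarely commit to a "definitely" response,
    which leaves headroom for aid-induced confidence changes at both ends of
    the scale.
    """

    n_pairs: int = 160
    mismatch_prevalence: float = 0.10
    n_participants: int = 100
    d_true: float = 1.5
    tau_pair: float = 0.5
    afr_link: AfrLink = field(default_factory=AfrLink)
    base_criteria: tuple[float, ...] = (-1.0, -0.1, 0.75, 2.0, 3.5)
    drift_max_binary: float = 0.6
    drift_max_graded: float = 0.25
    drift_tau_binary: float = 20.0
    drift_tau_graded: float = 120.0
    w_graded: float = 2.0
    w_binary: float = 1.0
    aid_noise_sd: float = 0.8
    obs_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mismatch_prevalence <= 0.5:
            raise ValueError(
                f"mismatch_prevalence={self.mismatch_prevalence} outside (0, 0.5]"
            )
        if round(self.n_pairs * self.mismatch_prevalence) < 1:
            raise ValueError("design needs at least one mismatch pair")
        cuts = np.asarray(self.base_criteria, dtype=float)
        if cuts.size != 5 or np.any(np.diff(cuts) <= 0):
            raise ValueError("base_criteria must be 5 strictly increasing cutpoints")
        if not self.drift_max_binary > self.drift_max_graded >= 0:
            raise ValueError("require drift_max_binary > drift_max_graded >= 0")
        if not self.drift_tau_binary < self.drift_tau_graded:
            raise ValueError("require drift_tau_binary < drift_tau_graded")
        if self.obs_noise_sd <= 0 or self.aid_noise_sd < 0:
            raise ValueError("noise SDs must be positive (aid noise may be 0)")

    def drift_max(self, regime: str) -> float:
        # no-feedback observers drift like binary-feedback ones: prevalence,
        # not the aid, is the driver, and graded similarity is what tempers it
        return self.drift_max_graded if regime == "graded" else self.drift_max_binary

    def drift_tau(self, regime: str) -> float:
        return self.drift_tau_graded if regime == "graded" else self.drift_tau_binary


def _check_regime(regime: str) -> str:
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    return regime


def generate_face_set(
    params: GeneratorParams, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a face set with latent evidence and AFR similarity per pair.

    Exactly ``round(n_pairs * mismatch_prevalence)`` pairs are mismatches.
    Latent evidence ``theta ~ N(d_true, tau_pair^2)`` for matches and
    ``N(0, tau_pair^2)`` for mismatches.  The AFR raw score is
    ``0.3 + 0.7 * sigmoid(slope * (theta + zeta))`` for matches and
    ``-0.1 + 0.4 * sigmoid(slope * (theta + zeta))`` for mismatches with
    ``zeta ~ N(0, noise_sd^2)``, so every pair is classified correctly at
    the 0.3 threshold by construction.  Ethnicity labels are metadata only.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_pairs
    n_mis = int(round(n * params.mismatch_prevalence))
    is_match = np.ones(n, dtype=bool)
    is_match[:n_mis] = False
    rng.shuffle(is_match)

    theta = rng.normal(0.0, params.tau_pair, size=n)
    theta[is_match] += params.d_true
    zeta = rng.normal(0.0, params.afr_link.noise_sd, size=n)
    s = expit(params.afr_link.slope * (theta + zeta))
    afr_raw = np.where(is_match, 0.3 + 0.7 * s, -0.1 + 0.4 * s)

    labels = list(ETHNICITY_PROPORTIONS)
    counts = np.array([int(round(p * n)) for p in ETHNICITY_PROPORTIONS.values()])
    counts[-1] += n - counts.sum()  # absorb rounding into the last category
    ethnicity = np.repeat(labels, counts)
    rng.shuffle(ethnicity)

    return pd.DataFrame(
        {
            "pair_id": [f"pair{str(i).zfill(3)}" for i in range(n)],
            "is_match": is_match,
            "theta": theta,
            "afr_raw": afr_raw,
            "afr_displayed": transform_similarity(afr_raw),
            "ethnicity": ethnicity,
        }
    )


def drifted_cutpoints(
    base_criteria, t, regime: str, params: GeneratorParams
) -> np.ndarray:
    """Rating cutpoints after criterion drift at 0-based trial index ``t``.

    All five cutpoints shift down together by
    ``drift_max * (1 - exp(-t / drift_tau))``; lowering the cutpoints makes
    "same" responses more likely (a liberal shift).  ``t`` may be an array,
    in which case the result has shape ``(len(t), 5)``.
    """
    _check_regime(regime)
    base = np.asarray(base_criteria, dtype=float)
    t = np.asarray(t, dtype=float)
    shift = params.drift_max(regime) * (1.0 - np.exp(-t / params.drift_tau(regime)))
    return base - np.expand_dims(shift, -1) if t.ndim else base - shift


def simulate_unaided_rating(
    theta: float,
    cutpoints_t,
    rng: np.random.Generator,
    obs_noise_sd: float = 1.0,
):
    """Sample a 1-6 rating from the equal-variance observer.

    Evidence ``e = theta + N(0, obs_noise_sd)``; the rating is 1 plus the
    number of cutpoints below ``e``.  ``cutpoints_t`` must already include
    any drift shift for the trial.  ``theta`` may be an array (one evidence
    sample per element; ``cutpoints_t`` then broadcasts or is per-trial).
    """
    cuts = np.asarray(cutpoints_t, dtype=float)
    if np.any(np.diff(cuts, axis=-1) <= 0):
        raise ValueError("cutpoints must be strictly ascending")
    theta = np.asarray(theta, dtype=float)
    e = theta + rng.normal(0.0, obs_noise_sd, size=theta.shape)
    rating = 1 + (np.expand_dims(e, -1) > cuts).sum(axis=-1)
    return int(rating) if rating.ndim == 0 else rating.astype(int)


def simulate_aided_rating(
    unaided_rating,
    displayed,
    is_match,
    regime: str,
    params: GeneratorParams,
    rng: np.random.Generator,
):
    """Re-rating after seeing the AFR output.

    * graded: the shift is ``w_graded * 2 * (displayed - 0.5)`` — zero at
      the displayed threshold, growing with the AFR's confidence and signed
      toward the AFR's decision;
    * binary: a constant ``+w_binary`` when the AFR says match, else
      ``-w_binary``.

    Gaussian jitter ``N(0, aid_noise_sd)`` is added before rounding and
    clipping to the 1-6 scale.
    """
    _check_regime(regime)
    if regime == "none":
        raise ValueError("regime 'none' has no aided ratings")
    u = np.asarray(unaided_rating, dtype=float)
    if regime == "graded":
        shift = params.w_graded * 2.0 * (np.asarray(displayed, dtype=float) - 0.5)
    else:
        shift = np.where(np.asarray(is_match, dtype=bool), params.w_binary, -params.w_binary)
    noise = rng.normal(0.0, params.aid_noise_sd, size=u.shape)
    rating = np.clip(np.rint(u + shift + noise), 1, 6)
    return int(rating) if rating.ndim == 0 else rating.astype(int)


def _trust_and_estimates(
    rng: np.random.Generator, n: int, acc_unaided, acc_aided
) -> pd.DataFrame:
    """Participant questionnaire block: plumbing, not a psychological model.

    Self-estimates are the participant's accuracy plus reporting noise;
    trust items are exchangeable 1-5 responses (individual differences in
    trust are deliberately not modelled).
    """
    items = rng.integers(1, 6, size=(n, 10))
    self_est = np.clip(np.round(100 * acc_unaided + rng.normal(0, 8, n)), 0, 100)
    afr_est = np.clip(np.round(90 + rng.normal(0, 8, n)), 0, 100)
    df = pd.DataFrame(items, columns=[f"trust_item_{i + 1:02d}" for i in range(10)])
    df["self_estimate"] = self_est
    df["afr_estimate"] = afr_est
    return df


def simulate_experiment(
    params: GeneratorParams,
    regime: str,
    seed: int | None = None,
    face_set: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one whole experiment in the given information regime.

    Every participant rates the same face set (drawn once per experiment)
    in an independently shuffled order, once unaided and — in regimes
    ``graded`` and ``binary`` — once aided.  Returns ``(trials,
    participants, truth)``: a tidy trial table in the canonical CSV schema,
    a participant table with questionnaire columns, and the ground-truth
    generator parameters for recovery tests.
    """
    _check_regime(regime)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if face_set is None:
        face_set = generate_face_set(params, rng)
    n_p, n_t = params.n_participants, params.n_pairs
    theta = face_set["theta"].to_numpy()
    displayed = face_set["afr_displayed"].to_numpy()
    is_match = face_set["is_match"].to_numpy(dtype=bool)

    # per-participant shuffled presentation order: orders[i, t] = pair shown
    # at (0-based) position t for participant i
    orders = np.array([rng.permutation(n_t) for _ in range(n_p)])
    cuts_t = drifted_cutpoints(params.base_criteria, np.arange(n_t), regime, params)
    evidence = theta[orders] + rng.normal(0.0, params.obs_noise_sd, size=(n_p, n_t))
    unaided = 1 + (evidence[:, :, None] > cuts_t[None, :, :]).sum(axis=-1)

    if regime != "none":
        aided = simulate_aided_rating(
            unaided, displayed[orders], is_match[orders], regime, params, rng
        )

    pid = np.array([f"p{str(i).zfill(3)}" for i in range(n_p)])
    base = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, n_t),
            "experiment": _EXPERIMENT_LABEL[regime],
            "regime": regime,
            "presentation_index": np.tile(np.arange(1, n_t + 1), n_p),
            "pair_id": face_set["pair_id"].to_numpy()[orders].ravel(),
            "is_match": is_match[orders].ravel().astype(int),
            "is_attention_check": 0,
            "afr_raw": face_set["afr_raw"].to_numpy()[orders].ravel(),
            "afr_displayed": displayed[orders].ravel(),
            "afr_decision": is_match[orders].ravel().astype(int),
        }
    )
    tables = []
    for cond, ratings in (
        [("unaided", unaided)] + ([("aided", aided)] if regime != "none" else [])
    ):
        tab = base.copy()
        tab["condition"] = cond
        tab["rating"] = ratings.ravel()
        tables.append(tab)
    trials = pd.concat(tables, ignore_index=True)
    col_order = [
        "participant_id", "experiment", "regime", "condition",
        "presentation_index", "pair_id", "is_match", "is_attention_check",
        "rating", "afr_raw", "afr_displayed", "afr_decision",
    ]
    trials = trials[col_order]

    same = unaided >= 4
    acc_unaided = (same == is_match[orders]).mean(axis=1)
    if regime != "none":
        acc_aided = ((aided >= 4) == is_match[orders]).mean(axis=1)
    else:
        acc_aided = np.full(n_p, np.nan)
    participants = pd.DataFrame(
        {"participant_id": pid, "experiment": _EXPERIMENT_LABEL[regime], "regime": regime}
    )
    participants = pd.concat(
        [participants, _trust_and_estimates(rng, n_p, acc_unaided, acc_aided)], axis=1
    )

    truth = {
        "params": params,
        "regime": regime,
        "face_set": face_set,
        "d_prime_analytic": analytic_dprime(params),
    }
    return trials, participants, truth


def simulate_study(
    params: GeneratorParams,
    regimes=("graded", "binary", "none"),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate several information regimes over one shared face set.

    Mirrors the study design: every experiment presents the same 160 pairs
    to its own cohort.  Participant ids are prefixed with the experiment
    label so the concatenated tables stay unique.  Returns the combined
    trial and participant tables plus the shared ground truth.
    """
    root = np.random.default_rng(params.seed if seed is None else seed)
    face_set = generate_face_set(params, root)
    trial_tabs, part_tabs = [], []
    truth: dict = {}
    for regime in regimes:
        sub_seed = int(root.integers(2**31 - 1))
        tr, pa, truth = simulate_experiment(params, regime, sub_seed, face_set)
        label = _EXPERIMENT_LABEL[regime]
        tr["participant_id"] = label + "_" + tr["participant_id"]
        pa["participant_id"] = label + "_" + pa["participant_id"]
        trial_tabs.append(tr)
        part_tabs.append(pa)
    return (
        pd.concat(trial_tabs, ignore_index=True),
        pd.concat(part_tabs, ignore_index=True),
        truth,
    )


def analytic_dprime(params: GeneratorParams) -> float:
    """Population d' implied by the generator with the drift switched off.

    Evidence on a random trial is normal with SD
    ``sqrt(tau_pair^2 + obs_noise_sd^2)`` around ``d_true`` (match) or 0
    (mismatch); the binary decision uses the middle cutpoint, so
    ``d' = z(H) - z(F)`` with H and F the corresponding tail probabilities.
    """
    s = float(np.hypot(params.tau_pair, params.obs_noise_sd))
    c = params.base_criteria[2]
    h = norm.sf(c, loc=params.d_true, scale=s)
    f = norm.sf(c, loc=0.0, scale=s)
    return float(ndtri(h) - ndtri(f))


def with_no_drift(params: GeneratorParams) -> GeneratorParams:
    """Copy of ``params`` with criterion drift effectively disabled."""
    return replace(params, drift_max_binary=1e-12, drift_max_graded=0.0)
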