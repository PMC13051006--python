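"""End-to-end orchestration: I/O, exclusions, and the full report bundle.

Canonical trial-table CSV dialect: UTF-8, comma-separated, header row,
columns ``participant_id, experiment, regime, condition,
presentation_index, pair_id, is_match, is_attention_check, rating, afr_raw,
afr_displayed, afr_decision``; booleans as 0/1, missing values as empty
fields.  Real data exports should be mapped onto this schema by the user; the
package defines the dialect rather than guessing a deposit's layout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .scores import adherence, cic, cronbach_alpha, pair_mean_cic, trust_score
from .sdt import overall_accuracy, quarter_criteria, sdt_table
from .stats import (
    cic_similarity_regression,
    correlation_table,
    mixed_anova_2x2,
    oneway_anova,
    table1,
    welch_t,
)

__all__ = [
    "TRIAL_COLUMNS",
    "RunConfig",
    "ExclusionReport",
    "read_trials",
    "read_participants",
    "write_trials",
    "apply_exclusions",
    "ci95",
    "run_full",
]

TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "regime",
    "condition",
    "presentation_index",
    "pair_id",
    "is_match",
    "is_attention_check",
    "rating",
    "afr_raw",
    "afr_displayed",
    "afr_decision",
]

EXCLUSION_FLAGS = [
    "polish_media_familiar",
    "attention_check_failed",
    "duration_out_of_range",
    "incomplete",
    "duplicate_start",
]

#: inclusion window for study duration, minutes
DURATION_MIN, DURATION_MAX = 7.0, 60.0


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    trials_path: str | Path | None = None
    participants_path: str | Path | None = None
    out_dir: str | Path = "afrmatch_out"
    n_quarters: int = 4
    split_half_n_splits: int = 100
    reverse_coded_trust_items: tuple[int, ...] = ()
    seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "reverse_coded_trust_items" in raw:
            raw["reverse_coded_trust_items"] = tuple(raw["reverse_coded_trust_items"])
        return cls(**raw)


@dataclass
class ExclusionReport:
    """Per-participant exclusion flags and the counts per flag."""

    flags: pd.DataFrame  # participant_id, one bool column per flag, included
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_included(self) -> int:
        return int(self.flags["included"].sum())

    @property
    def n_excluded(self) -> int:
        return int((~self.flags["included"]).sum())


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a canonical trial-table CSV.

    Unknown extra columns are carried through with a warning; schema
    violations raise with the offending row numbers (0-based, excluding the
    header).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        import warnings

        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)

    def _bad_rows(mask, what):
        if mask.any():
            rows = df.index[mask][:10].tolist()
            raise ValueError(f"{path}: {what} at rows {rows}")

    _bad_rows(~df["rating"].isin(range(1, 7)), "rating outside 1..6")
    _bad_rows(~df["condition"].isin(["unaided", "aided"]), "unknown condition")
    _bad_rows(~df["is_match"].isin([0, 1]), "is_match must be 0/1")
    _bad_rows(~df["is_attention_check"].isin([0, 1]), "is_attention_check must be 0/1")
    status = df.groupby("pair_id")["is_match"].nunique()
    incons = status[status > 1].index.tolist()
    if incons:
        raise ValueError(f"{path}: pairs with inconsistent match status: {incons[:10]}")
    dup = df.duplicated(["participant_id", "pair_id", "condition"])
    _bad_rows(dup, "duplicate (participant, pair, condition)")
    df["is_match"] = df["is_match"].astype(bool)
    df["is_attention_check"] = df["is_attention_check"].astype(bool)
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table in the canonical dialect (booleans as 0/1)."""
    out = trials.copy()
    for col in ("is_match", "is_attention_check", "afr_decision"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: participant table needs a participant_id column")
    return df


def apply_exclusions(
    trials: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, ExclusionReport]:
    """Apply the study's participant exclusion rules.

    A participant is excluded when any flag is set:

    * ``polish_media_familiar`` — familiarity with the Polish media
      personalities used as match stimuli (participant-table column);
    * ``attention_check_failed`` — *both* attention-check pairs answered
      incorrectly (one failure is tolerated); judged on the unaided rating;
    * ``duration_out_of_range`` — completion time outside 7-60 minutes
      (participant-table column ``duration_min``);
    * ``incomplete`` / ``duplicate_start`` — participant-table columns.

    Attention-check trials are removed from the included participants'
    data so every downstream computation sees experimental pairs only.
    """
    pids = pd.Index(trials["participant_id"].unique(), name="participant_id")
    flags = pd.DataFrame(False, index=pids, columns=EXCLUSION_FLAGS)

    checks = trials[trials["is_attention_check"] & (trials["condition"] == "unaided")]
    if len(checks):
        correct = (checks["rating"] >= 4) == checks["is_match"]
        by_p = correct.groupby(checks["participant_id"]).agg(["sum", "size"])
        failed_both = by_p.index[(by_p["size"] - by_p["sum"]) >= 2]
        flags.loc[flags.index.intersection(failed_both), "attention_check_failed"] = True

    if participants is not None:
        ptab = participants.set_index("participant_id")
        common = flags.index.intersection(ptab.index)
        if "duration_min" in ptab.columns:
            dur = ptab.loc[common, "duration_min"].astype(float)
            bad = dur.index[(dur < DURATION_MIN) | (dur > DURATION_MAX)]
            flags.loc[bad, "duration_out_of_range"] = True
        for col in ("polish_media_familiar", "incomplete", "duplicate_start"):
            if col in ptab.columns:
                bad = common[ptab.loc[common, col].fillna(0).astype(bool)]
                flags.loc[bad, col] = True

    flags["included"] = ~flags[EXCLUSION_FLAGS].any(axis=1)
    keep = flags.index[flags["included"]]
    trials_out = trials[
        trials["participant_id"].isin(keep) & ~trials["is_attention_check"]
    ].reset_index(drop=True)
    participants_out = None
    if participants is not None:
        participants_out = participants[
            participants["participant_id"].isin(keep)
        ].reset_index(drop=True)
    counts = {c: int(flags[c].sum()) for c in EXCLUSION_FLAGS}
    return trials_out, participants_out, ExclusionReport(flags.reset_index(), counts)


def ci95(values) -> tuple[float, float]:
    """Mean and 95% CI half-width using the t critical value.

    A single value (or zero) has no defined interval: half-width is ``nan``.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return float("nan"), float("nan")
    if x.size == 1:
        return float(x[0]), float("nan")
    half = sps.t.ppf(0.975, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
    return float(x.mean()), float(half)


def _participant_summaries(
    trials: pd.DataFrame, participants: pd.DataFrame | None, config: RunConfig
) -> pd.DataFrame:
    """Per-participant accuracies, adherence, trust and estimates."""
    rows = []
    for pid, grp in trials.groupby("participant_id"):
        un = grp[grp["condition"] == "unaided"]
        ai = grp[grp["condition"] == "aided"]
        acc_un = overall_accuracy(un["rating"].to_numpy(), un["is_match"].to_numpy())
        rec = {"participant_id": pid, "acc_unaided": acc_un}
        if len(ai):
            acc_ai = overall_accuracy(ai["rating"].to_numpy(), ai["is_match"].to_numpy())
            rec["acc_aided"] = acc_ai
            rec["adherence"] = adherence(acc_ai, acc_un)
        rows.append(rec)
    summ = pd.DataFrame(rows)
    if participants is not None:
        item_cols = [f"trust_item_{i:02d}" for i in range(1, 11)]
        ptab = participants.copy()
        if all(c in ptab.columns for c in item_cols):
            ptab["trust"] = [
                trust_score(r, reverse_coded=config.reverse_coded_trust_items)
                for r in ptab[item_cols].to_numpy()
            ]
        keep = [
            c
            for c in ("participant_id", "trust", "self_estimate", "afr_estimate")
            if c in ptab.columns
        ]
        summ = summ.merge(ptab[keep], on="participant_id", how="left")
    return summ


def _fig_data(trials: pd.DataFrame, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Per-figure data tables (means with 95% CIs, trajectories, CIC)."""
    out: dict[str, pd.DataFrame] = {}
    per_part = sdt_table(trials, by=("experiment", "participant_id", "condition"))
    out["participant_sdt"] = per_part

    # accuracy split by pair type: one accuracy per participant x faceType
    acc_rows = []
    for (exp, cond, m), grp in trials.groupby(["experiment", "condition", "is_match"]):
        accs = (
            grp.assign(correct=((grp["rating"] >= 4) == grp["is_match"]).astype(float))
            .groupby("participant_id")["correct"]
            .mean()
        )
        mean, half = ci95(accs.to_numpy())
        acc_rows.append(
            {
                "experiment": exp,
                "condition": cond,
                "pair_type": "match" if m else "mismatch",
                "mean_accuracy": mean,
                "ci95_half_width": half,
                "n": len(accs),
            }
        )
    out["fig1_accuracy"] = pd.DataFrame(acc_rows)

    sdt_rows = []
    for (exp, cond), grp in per_part.groupby(["experiment", "condition"]):
        for measure in ("d_prime", "criterion"):
            mean, half = ci95(grp[measure].to_numpy())
            sdt_rows.append(
                {
                    "experiment": exp,
                    "condition": cond,
                    "measure": measure,
                    "mean": mean,
                    "ci95_half_width": half,
                    "n": len(grp),
                }
            )
    out["fig2_sdt"] = pd.DataFrame(sdt_rows)

    q_rows = []
    unaided = trials[trials["condition"] == "unaided"]
    for (exp, pid), grp in unaided.groupby(["experiment", "participant_id"]):
        qs = quarter_criteria(
            grp["rating"].to_numpy(),
            grp["is_match"].to_numpy(),
            grp["presentation_index"].to_numpy(),
            n_quarters=config.n_quarters,
        )
        for q, c in enumerate(qs, start=1):
            q_rows.append(
                {"experiment": exp, "participant_id": pid, "quarter": q, "criterion": c}
            )
    qdf = pd.DataFrame(q_rows)
    traj = (
        qdf.groupby(["experiment", "quarter"])["criterion"]
        .agg(
            mean_criterion="mean",
            sem=lambda v: v.dropna().std(ddof=1) / np.sqrt(v.notna().sum()),
            n_defined=lambda v: v.notna().sum(),
        )
        .reset_index()
    )
    out["fig3_quarters"] = traj

    cic_frames, reg_rows = [], []
    for exp, grp in trials.groupby("experiment"):
        if not (grp["condition"] == "aided").any():
            continue
        pm = pair_mean_cic(grp)
        pm.insert(0, "experiment", exp)
        cic_frames.append(pm)
        for m in (True, False):
            sub = pm[pm["is_match"] == m]
            slope, r, df_, p = cic_similarity_regression(
                sub["mean_cic"].to_numpy(), sub["afr_displayed"].to_numpy()
            )
            reg_rows.append(
                {
                    "experiment": exp,
                    "pair_type": "match" if m else "mismatch",
                    "slope": slope,
                    "r": r,
                    "df": df_,
                    "p": p,
                }
            )
    if cic_frames:
        out["fig4_cic"] = pd.concat(cic_frames, ignore_index=True)
        out["fig4_regressions"] = pd.DataFrame(reg_rows)

    crit_rows = []
    un_crit = per_part[per_part["condition"] == "unaided"]
    for exp, grp in un_crit.groupby("experiment"):
        mean, half = ci95(grp["criterion"].to_numpy())
        crit_rows.append(
            {
                "experiment": exp,
                "mean_criterion": mean,
                "ci95_half_width": half,
                "n": len(grp),
            }
        )
    out["fig5_criterion"] = pd.DataFrame(crit_rows)
    return out


def _stat_panel(per_part: pd.DataFrame) -> pd.DataFrame:
    """ANOVA / t-test panel across experiments, where the design allows."""
    rows = []
    aided_exps = [
        e
        for e, g in per_part.groupby("experiment")
        if set(g["condition"]) >= {"unaided", "aided"}
    ]
    if len(aided_exps) == 2:
        wide = per_part[per_part["experiment"].isin(aided_exps)].pivot_table(
            index=["experiment", "participant_id"],
            columns="condition",
            values=["d_prime", "criterion"],
        )
        for measure in ("d_prime", "criterion"):
            res = mixed_anova_2x2(
                wide[(measure, "unaided")].to_numpy(),
                wide[(measure, "aided")].to_numpy(),
                wide.index.get_level_values("experiment").to_numpy(),
            )
            for eff_name, eff in (
                ("experiment", res.between),
                ("aid", res.within),
                ("interaction", res.interaction),
            ):
                rows.append(
                    {
                        "analysis": f"mixed_anova_{measure}",
                        "effect": eff_name,
                        "F": eff.F,
                        "df1": eff.df1,
                        "df2": eff.df2,
                        "p": eff.p,
                        "partial_eta_sq": eff.partial_eta_sq,
                    }
                )
    un = per_part[per_part["condition"] == "unaided"]
    if un["experiment"].nunique() >= 2:
        for measure in ("d_prime", "criterion"):
            eff = oneway_anova(un[measure].to_numpy(), un["experiment"].to_numpy())
            rows.append(
                {
                    "analysis": f"oneway_unaided_{measure}",
                    "effect": "experiment",
                    "F": eff.F,
                    "df1": eff.df1,
                    "df2": eff.df2,
                    "p": eff.p,
                    "partial_eta_sq": eff.partial_eta_sq,
                }
            )
        exps = sorted(un["experiment"].unique())
        for i, a in enumerate(exps):
            for b in exps[i + 1 :]:
                t, df_, p, d = welch_t(
                    un.loc[un["experiment"] == a, "criterion"].to_numpy(),
                    un.loc[un["experiment"] == b, "criterion"].to_numpy(),
                )
                rows.append(
                    {
                        "analysis": f"welch_criterion_{a}_vs_{b}",
                        "effect": "experiment",
                        "F": np.nan,
                        "df1": np.nan,
                        "df2": df_,
                        "p": p,
                        "t": t,
                        "cohen_d": d,
                    }
                )
    return pd.DataFrame(rows)


def run_full(
    trials: pd.DataFrame | None = None,
    participants: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every analysis stage and write the report bundle.

    Tables may be passed in memory or read from the paths in ``config``.
    Writes one CSV per report table under ``config.out_dir`` plus a
    machine-readable ``run_log.json`` and returns the tables as a dict.
    """
    config = config or RunConfig()
    stage = "load"
    try:
        if trials is None:
            if config.trials_path is None:
                raise ValueError("no trial table given (in memory or via config)")
            trials = read_trials(config.trials_path)
        if participants is None and config.participants_path is not None:
            participants = read_participants(config.participants_path)

        stage = "exclusions"
        trials, participants, report = apply_exclusions(trials, participants, config)
        if not len(trials):
            raise ValueError("no trials left after exclusions")

        stage = "figures"
        bundle = _fig_data(trials, config)

        stage = "statistics"
        bundle["stat_panel"] = _stat_panel(bundle["participant_sdt"])
        summaries = _participant_summaries(trials, participants, config)
        bundle["participant_summaries"] = summaries
        t1_cols = [
            c
            for c in (
                "trust",
                "self_estimate",
                "afr_estimate",
                "acc_unaided",
                "acc_aided",
                "adherence",
            )
            if c in summaries.columns and summaries[c].notna().sum() >= 3
        ]
        if len(t1_cols) >= 2:
            bundle["table1"] = table1(summaries[t1_cols])
        if participants is not None:
            item_cols = [f"trust_item_{i:02d}" for i in range(1, 11)]
            if all(c in participants.columns for c in item_cols):
                alpha = cronbach_alpha(participants[item_cols].to_numpy())
                bundle["trust_scale"] = pd.DataFrame(
                    [{"cronbach_alpha": alpha, "n": len(participants)}]
                )

        stage = "correlation_table"
        un = trials[trials["condition"] == "unaided"]
        exps = sorted(un["experiment"].unique())
        mats, sim, match_mask, pair_index = {}, None, None, None
        for exp in exps:
            sub = un[un["experiment"] == exp]
            mat = sub.pivot_table(index="participant_id", columns="pair_id", values="rating")
            if mat.isna().any().any() or mat.shape[0] < 4:
                continue
            if pair_index is None:
                pair_index = mat.columns
                meta = sub.drop_duplicates("pair_id").set_index("pair_id")
                sim = meta.loc[pair_index, "afr_displayed"].to_numpy()
                match_mask = meta.loc[pair_index, "is_match"].to_numpy(dtype=bool)
            if mat.columns.equals(pair_index):
                mats[f"{exp}_rating"] = mat.to_numpy()
        if len(mats) >= 1 and pair_index is not None:
            for label, mask in (("match", match_mask), ("mismatch", ~match_mask)):
                sub_mats = {k: v[:, mask] for k, v in mats.items()}
                tab = correlation_table(
                    sub_mats,
                    afr_similarity=sim[mask],
                    n_splits=config.split_half_n_splits,
                    seed=config.seed,
                )
                bundle[f"table2_{label}"] = tab.reset_index(names="measure")

        bundle["exclusions"] = report.flags

        stage = "write"
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        log = {
            "package": "afrmatch",
            "version": __version__,
            "seed": config.seed,
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "n_included": report.n_included,
            "n_excluded": report.n_excluded,
            "exclusion_counts": report.counts,
            "tables": sorted(bundle),
        }
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
        if config.make_plots:
            stage = "plots"
            _render_plots(bundle, out_dir)
        return bundle
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err


def _render_plots(bundle: dict[str, pd.DataFrame], out_dir: Path) -> None:
    """Optional quick-look figures; the CSVs remain the authoritative output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "fig3_quarters" in bundle:
        fig, ax = plt.subplots()
        for exp, grp in bundle["fig3_quarters"].groupby("experiment"):
            ax.errorbar(
                grp["quarter"], grp["mean_criterion"], yerr=grp["sem"], label=exp,
                marker="o",
            )
        ax.set_xlabel("quarter of trials")
        ax.set_ylabel("mean unaided criterion C")
        ax.legend()
        fig.savefig(out_dir / "fig3_quarters.png", dpi=120)
        plt.close(fig)
    if "fig4_cic" in bundle:
        fig, ax = plt.subplots()
        for (exp, m), grp in bundle["fig4_cic"].groupby(["experiment", "is_match"]):
            ax.scatter(
                grp["afr_displayed"], grp["mean_cic"], s=12,
                label=f"{exp} {'match' if m else 'mismatch'}",
            )
        ax.set_xlabel("displayed AFR similarity")
        ax.set_ylabel("mean change in confidence")
        ax.legend(fontsize=7)
        fig.savefig(out_dir / "fig4_cic.png", dpi=120)
        plt.close(fig)
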