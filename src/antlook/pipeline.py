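"""End-to-end analysis pipeline and run report.

``run`` takes a :class:`RunConfig` describing either recorded fixation
data (tidy CSV plus a participant-metadata CSV) or simulation parameters,
and produces a report mirroring the study's results structure: the
exclusion ledger by site, second-familiarization anticipation, test-trial
first-look counts with exact binomial and Fisher tests, DLS descriptives
with one-sample and Welch t-tests, and the condition x inclusion ANOVA on
the extended sample.  Supplementary analysis variants are flags:

* ``period_1750``          — score first look and DLS over 1750 ms
  (the originally reported period) instead of 2750 ms;
* ``no_lookaway_criteria`` — drop the familiarization-attention and
  test look-away exclusion criteria;
* ``require_head_first``   — restrict analysis samples to participants
  who fixated the agent's head before their first window+box look;
* ``duration_anova``       — add the mixed ANOVA on correct/incorrect
  window looking durations.

The JSON report is deterministic (sorted keys, fixed float handling):
re-running with identical config and inputs reproduces it byte for byte.
Every number in the human-readable rendering is drawn from the JSON
report, and all thresholds and statistical conventions are echoed for
audit, since exactly such conventions tend to drive replication disputes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .cohort import (
    ExclusionThresholds,
    RawParticipant,
    apply_exclusions,
    build_record,
    measure_table,
)
from .events import ConfigError, read_csv_fixations
from .paradigm import load_aois, load_paradigm_config
from .simulate import SimulationParams, simulate_cohort

log = logging.getLogger("antlook")

METADATA_COLUMNS = ("participant", "site", "condition", "procedural_error")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``fixations_csv`` (+ ``participants_csv``) or
    ``simulation`` must be given.
    """

    fixations_csv: str | None = None
    participants_csv: str | None = None
    simulation: SimulationParams | None = None
    paradigm_config: str | None = None
    thresholds: ExclusionThresholds = field(default_factory=ExclusionThresholds)
    lookaway_merge_tolerance: int = 0
    period_1750: bool = False
    no_lookaway_criteria: bool = False
    require_head_first: bool = False
    duration_anova: bool = False
    output_dir: str | None = None
    make_figures: bool = True

    def __post_init__(self) -> None:
        has_files = self.fixations_csv is not None
        if has_files == (self.simulation is not None):
            raise ConfigError(
                "exactly one of fixations_csv / simulation must be provided"
            )
        if has_files and self.participants_csv is None:
            raise ConfigError("fixations_csv requires participants_csv")
        if self.lookaway_merge_tolerance < 0:
            raise ConfigError("lookaway_merge_tolerance must be >= 0")


def _load_recorded(config: RunConfig) -> list[RawParticipant]:
    sequences = read_csv_fixations(config.fixations_csv)
    meta = pd.read_csv(config.participants_csv)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ConfigError(f"participants CSV missing column(s): {', '.join(missing)}")
    by_participant: dict[str, dict] = {}
    for seq in sequences:
        by_participant.setdefault(seq.participant, {})[seq.trial_role] = seq
    out = []
    for row in meta.itertuples():
        pid = str(row.participant)
        out.append(
            RawParticipant(
                participant=pid,
                site=str(row.site),
                condition=str(row.condition),
                procedural_error=bool(row.procedural_error),
                sequences=by_participant.get(pid, {}),
            )
        )
    return out


def _test_result_block(res: stats.TestResult | None, note: str | None = None) -> dict:
    if res is None:
        return {"computable": False, "note": note or "insufficient data"}
    block = {"computable": True, **res.to_dict()}
    if note:
        block["note"] = note
    return block


def _anova_block(table: pd.DataFrame | None, note: str | None = None) -> dict:
    if table is None:
        return {"computable": False, "note": note or "insufficient data"}
    return {
        "computable": True,
        "effects": {
            str(idx): {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            for idx, row in table.iterrows()
        },
    }


def _try(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs), None
    except stats.StatsError as exc:
        return None, str(exc)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the JSON-ready run report.

    If ``config.output_dir`` is set, also writes ``report.json``,
    ``report.txt``, ``measures.csv``, ``ledger.csv``,
    ``ledger_summary.json`` and (optionally) figures there.
    """
    paradigm = load_paradigm_config(config.paradigm_config)
    aois = load_aois(paradigm)
    poi = 1750 if config.period_1750 else None

    if config.simulation is not None:
        raws = simulate_cohort(config.simulation, paradigm)
    else:
        raws = _load_recorded(config)

    records = [
        build_record(
            raw, aois, paradigm,
            period_of_interest=poi,
            lookaway_merge_tolerance=config.lookaway_merge_tolerance,
        )
        for raw in raws
    ]

    thresholds = config.thresholds
    if config.no_lookaway_criteria:
        thresholds = ExclusionThresholds(
            thresholds.fam_cumulative_min,
            thresholds.test_lookaway_max,
            use_lookaway_criteria=False,
        )
    main, fam2_incorrect, ledger = apply_exclusions(records, thresholds)
    for pid, status in sorted(ledger.status.items()):
        log.info(
            "participant %s: %s%s", pid, status,
            f" ({ledger.reason[pid]})" if pid in ledger.reason else "",
        )

    table = measure_table({"included": main, "fam2_incorrect": fam2_incorrect})
    head_filtered = 0
    if config.require_head_first and not table.empty:
        head_filtered = int((~table["head_before_window"]).sum())
        table = table[table["head_before_window"]].reset_index(drop=True)

    report = {
        "conventions": {
            "two_tailed_exact": "point-probability (sum of outcomes no more likely than observed)",
            "anova_sum_of_squares": "Type III, sum-to-zero contrasts",
            "intervals": "half-open [onset, offset), integer ms",
            "first_look": "fixation onset within period of interest; window+box AOIs; landing point",
            "dls": "window-only AOIs, fixations clipped to period of interest",
            "period_of_interest_ms": 1750 if config.period_1750 else 2750,
            "fam_cumulative_min_ms": thresholds.fam_cumulative_min,
            "test_lookaway_max_ms": thresholds.test_lookaway_max,
            "lookaway_criteria_applied": thresholds.use_lookaway_criteria,
            "lookaway_merge_tolerance_ms": config.lookaway_merge_tolerance,
            "require_head_first": config.require_head_first,
            "head_first_filtered_out": head_filtered,
        },
        "exclusion_ledger": ledger.summary(),
    }

    inc = table[table["inclusion"] == "included"]
    n_pass_upstream = ledger.n_included + ledger.counts()["fam2_incorrect"]
    report["fam2_anticipation"] = {
        "n_passing_prior_criteria": n_pass_upstream,
        "n_correct": ledger.n_included,
        "proportion": (ledger.n_included / n_pass_upstream) if n_pass_upstream else None,
    }

    # test-trial first look: binomial against chance, Fisher between conditions
    n = len(inc)
    k = int(inc["first_look_correct"].sum())
    binom, binom_note = (
        _try(stats.exact_binomial_two_tailed, k, n, 0.5) if n else (None, "empty sample")
    )
    by_cond = {
        cond: {
            "n": int((inc["condition"] == cond).sum()),
            "n_correct": int(inc.loc[inc["condition"] == cond, "first_look_correct"].sum()),
        }
        for cond in ("FB1", "FB2")
    }
    fisher_table = [
        [by_cond["FB1"]["n_correct"], by_cond["FB1"]["n"] - by_cond["FB1"]["n_correct"]],
        [by_cond["FB2"]["n_correct"], by_cond["FB2"]["n"] - by_cond["FB2"]["n_correct"]],
    ]
    fisher, fisher_note = (
        _try(stats.fisher_exact_two_tailed, fisher_table)
        if min(by_cond["FB1"]["n"], by_cond["FB2"]["n"]) > 0
        else (None, "empty condition stratum")
    )
    report["test_first_look"] = {
        "n": n,
        "n_correct": k,
        "proportion": (k / n) if n else None,
        "by_condition": by_cond,
        "binomial_vs_chance": _test_result_block(binom, binom_note),
        "fisher_condition_by_correctness": _test_result_block(fisher, fisher_note),
    }

    # DLS battery
    dls_inc = inc["dls"].to_numpy(dtype=float)
    dls_block: dict = {
        "n_defined": int(np.isfinite(dls_inc).sum()),
        "n_undefined": int(np.isnan(dls_inc).sum()),
        "mean": float(np.nanmean(dls_inc)) if np.isfinite(dls_inc).any() else None,
    }
    t_all, note_all = _try(stats.one_sample_t, dls_inc, 0.5)
    dls_block["one_sample_t_vs_chance"] = _test_result_block(t_all, note_all)
    for cond in ("FB1", "FB2"):
        vals = inc.loc[inc["condition"] == cond, "dls"].to_numpy(dtype=float)
        res, note = _try(stats.one_sample_t, vals, 0.5)
        dls_block[f"one_sample_t_{cond}"] = _test_result_block(res, note)
        dls_block[f"mean_{cond}"] = (
            float(np.nanmean(vals)) if np.isfinite(vals).any() else None
        )
    welch, welch_note = _try(
        stats.welch_t,
        inc.loc[inc["condition"] == "FB1", "dls"].to_numpy(dtype=float),
        inc.loc[inc["condition"] == "FB2", "dls"].to_numpy(dtype=float),
    )
    dls_block["welch_t_fb1_vs_fb2"] = _test_result_block(welch, welch_note)
    report["dls"] = dls_block

    # extended-sample condition x inclusion ANOVA
    anova, anova_note = _try(
        stats.anova_2x2_between,
        table["dls"].to_numpy(dtype=float),
        table["condition"].tolist(),
        table["inclusion"].tolist(),
    ) if not table.empty else (None, "empty table")
    report["condition_by_inclusion_anova"] = _anova_block(anova, anova_note)

    if config.duration_anova:
        dur, dur_note = _try(
            stats.mixed_anova_duration,
            inc["correct_window_ms"].to_numpy(dtype=float),
            inc["incorrect_window_ms"].to_numpy(dtype=float),
            inc["condition"].tolist(),
        ) if n else (None, "empty sample")
        report["duration_mixed_anova"] = _anova_block(dur, dur_note)

    if config.output_dir is not None:
        _write_outputs(config, report, table, ledger)
    return report


def _write_outputs(config: RunConfig, report: dict, table: pd.DataFrame, ledger) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_json(report))
    (out / "report.txt").write_text(render_text_report(report))
    table.to_csv(out / "measures.csv", index=False)
    ledger.to_frame().to_csv(out / "ledger.csv", index=False)
    (out / "ledger_summary.json").write_text(
        json.dumps(ledger.summary(), indent=2, sort_keys=True)
    )
    if config.make_figures:
        from .figures import make_figures

        make_figures(report, table, out)


def report_json(report: dict) -> str:
    """Serialize the report deterministically (sorted keys, '\\n' newlines)."""
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n"


def _fmt_p(p: float | None) -> str:
    return "n/a" if p is None else f"{p:.3f}"


def _fmt_test(block: dict) -> str:
    if not block.get("computable"):
        return f"not computable ({block.get('note', 'insufficient data')})"
    bits = []
    if block.get("df") is not None:
        df = block["df"]
        bits.append(f"df={df:.2f}" if isinstance(df, (int, float)) else f"df={df}")
    stat = block.get("statistic")
    if stat is not None and np.isfinite(stat):
        bits.append(f"stat={stat:.3f}")
    bits.append(f"p={_fmt_p(block.get('p'))}")
    if block.get("ci95"):
        lo, hi = block["ci95"]
        bits.append(f"95%CI [{lo:.3f}, {hi:.3f}]")
    return ", ".join(bits)


def render_text_report(report: dict) -> str:
    """Human-readable rendering; every number comes from the JSON report."""
    lines: list[str] = []
    conv = report["conventions"]
    lines.append("Anticipatory-looking run report")
    lines.append("================================")
    lines.append(f"Period of interest: {conv['period_of_interest_ms']} ms from cue onset")
    lines.append(
        "Thresholds: fam attention >= "
        f"{conv['fam_cumulative_min_ms']} ms cumulative; test look-away <= "
        f"{conv['test_lookaway_max_ms']} ms consecutive "
        f"(applied: {conv['lookaway_criteria_applied']})"
    )
    lines.append(f"Two-tailed exact convention: {conv['two_tailed_exact']}")
    lines.append(f"ANOVA: {conv['anova_sum_of_squares']}")
    if conv["require_head_first"]:
        lines.append(
            f"Head-first filter applied; removed {conv['head_first_filtered_out']}"
        )
    led = report["exclusion_ledger"]
    lines.append("")
    lines.append(
        f"Exclusions: {led['total']} tested, {led['included']} included, "
        f"{led['excluded']} excluded"
    )
    for site, sled in sorted(led["by_site"].items()):
        reasons = ", ".join(f"{r}={c}" for r, c in sled["by_reason"].items() if c)
        lines.append(
            f"  {site}: {sled['total']} tested, {sled['included']} included"
            + (f" ({reasons})" if reasons else "")
        )
    fam2 = report["fam2_anticipation"]
    if fam2["proportion"] is not None:
        lines.append("")
        lines.append(
            f"Fam2 anticipation: {fam2['n_correct']} of "
            f"{fam2['n_passing_prior_criteria']} correct "
            f"({100 * fam2['proportion']:.0f}%)"
        )
    tfl = report["test_first_look"]
    lines.append("")
    lines.append(
        f"Test first look: {tfl['n_correct']} of {tfl['n']} correct; "
        f"binomial vs chance: {_fmt_test(tfl['binomial_vs_chance'])}"
    )
    for cond, c in sorted(tfl["by_condition"].items()):
        lines.append(f"  {cond}: {c['n_correct']} of {c['n']} correct")
    lines.append(
        f"  Fisher (condition x correctness): "
        f"{_fmt_test(tfl['fisher_condition_by_correctness'])}"
    )
    d = report["dls"]
    lines.append("")
    mean = "n/a" if d["mean"] is None else f"{d['mean']:.3f}"
    lines.append(
        f"DLS: mean={mean} (n={d['n_defined']} defined, "
        f"{d['n_undefined']} undefined)"
    )
    lines.append(f"  one-sample t vs 0.5: {_fmt_test(d['one_sample_t_vs_chance'])}")
    for cond in ("FB1", "FB2"):
        m = d.get(f"mean_{cond}")
        m_s = "n/a" if m is None else f"{m:.3f}"
        lines.append(
            f"  {cond}: mean={m_s}; t vs 0.5: {_fmt_test(d[f'one_sample_t_{cond}'])}"
        )
    lines.append(f"  Welch t FB1 vs FB2: {_fmt_test(d['welch_t_fb1_vs_fb2'])}")
    an = report["condition_by_inclusion_anova"]
    lines.append("")
    lines.append("Condition x inclusion ANOVA (extended sample):")
    if an.get("computable"):
        for eff, row in an["effects"].items():
            if eff == "residual":
                lines.append(f"  residual df={row['df']:.0f}")
            else:
                lines.append(
                    f"  {eff}: F={row['F']:.2f}, p={_fmt_p(row['p'])}"
                )
    else:
        lines.append(f"  not computable ({an.get('note')})")
    if "duration_mixed_anova" in report:
        an = report["duration_mixed_anova"]
        lines.append("")
        lines.append("Looking-duration mixed ANOVA (window x condition):")
        if an.get("computable"):
            for eff, row in an["effects"].items():
                lines.append(
                    f"  {eff}: F={row['F']:.2f} "
                    f"(df {row['df1']:.0f}, {row['df2']:.0f}), p={_fmt_p(row['p'])}"
                )
        else:
            lines.append(f"  not computable ({an.get('note')})")
    return "\n".join(lines) + "\n"
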