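"""Markdown summary assembled purely from pipeline artifacts.

The report never recomputes a statistic: every cell it prints is read from
the JSON/CSV artifacts a previous stage wrote, so regenerating the report
from the same artifacts is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .bones import N_GROUPS, RATIOS

_RATIO_LABEL = {"r43mc": "4:3 MC", "r53mc": "5:3 MC", "r53mp": "5:3 MP"}


def _fmt(x, nd=3):
    if x is None:
        return "–"
    return f"{x:.{nd}f}"


def generate_report(artifact_dir) -> str:
    """Compose report.md content from the artifact files in a directory."""
    d = Path(artifact_dir)
    lines = ["# Phalangeal-ratio pipeline report", ""]

    trim_path = d / "trim_summary.json"
    if trim_path.exists():
        trim = json.loads(trim_path.read_text())
        lines += [
            "## Outlier trimming",
            "",
            f"- subjects in: {trim['n_input']}",
            f"- excluded (any ratio |z| > limit): {trim['n_excluded_total']}",
            f"- retained: {trim['n_retained']}",
            "- per-ratio exclusions: "
            + ", ".join(
                f"{_RATIO_LABEL[r]}: {c}"
                for r, c in trim["n_excluded_per_ratio"].items()
            ),
            "",
        ]

    ref_path = d / "reference.json"
    if ref_path.exists():
        ref = json.loads(ref_path.read_text())
        lines += [
            f"## Normative reference table (trim limit {ref['trim_limit']} SDS)",
            "",
            "| group | "
            + " | ".join(f"{_RATIO_LABEL[r]} mean ± SD (n)" for r in RATIOS)
            + " |",
            "|---" * (1 + len(RATIOS)) + "|",
        ]
        for g in range(1, N_GROUPS + 1):
            cells = []
            for r in RATIOS:
                gs = ref["groups"][r][str(g)]
                cells.append(
                    f"{_fmt(gs['mean'])} ± {_fmt(gs['sd'])} ({gs['n']})"
                )
            lines.append(f"| {g} | " + " | ".join(cells) + " |")
        pooled_cells = [
            f"{_fmt(ref['pooled'][r]['mean'])} ± {_fmt(ref['pooled'][r]['sd'])} "
            f"({ref['pooled'][r]['n']})"
            for r in RATIOS
        ]
        lines += ["| pooled | " + " | ".join(pooled_cells) + " |", ""]

    prev_path = d / "prevalence.json"
    if prev_path.exists():
        prev = json.loads(prev_path.read_text())
        lines += ["## Screening flag prevalence", ""]
        for flag, entry in prev.items():
            prop = entry.get("proportion")
            pct = "n/a" if prop is None else f"{100 * prop:.1f}%"
            line = f"- {flag}: {entry['count']}/{entry['n']} ({pct})"
            comp = entry.get("comparison")
            if comp and "p_value" in comp:
                line += f" — vs comparison cohort: {comp['test']} p = {comp['p_value']:.3g}"
            lines.append(line)
        lines.append("")

    roc_path = d / "roc.json"
    if roc_path.exists():
        roc = json.loads(roc_path.read_text())
        lines += [
            "## ROC analysis of the 4:3 MC ratio",
            "",
            f"- AUC {_fmt(roc['auc'])} "
            f"(95% CI {_fmt(roc['auc_ci_low'])}–{_fmt(roc['auc_ci_high'])})",
            f"- Youden-optimal cutoff {_fmt(roc['youden_cutoff'])} "
            f"(J = {_fmt(roc['youden_j'])}; sensitivity "
            f"{_fmt(roc['sens_at_cutoff'])}, specificity {_fmt(roc['spec_at_cutoff'])})",
        ]
        fixed = roc.get("fixed_cutoff")
        if fixed:
            lines.append(
                f"- fixed cutoff {_fmt(fixed['cutoff'])}: sensitivity "
                f"{_fmt(fixed['sensitivity'])}, specificity {_fmt(fixed['specificity'])}"
            )
        lines.append(f"- orientation: {roc['orientation']}")
        lines.append("")

    screen_path = d / "screening.csv"
    if screen_path.exists():
        n = len(pd.read_csv(screen_path))
        lines += [f"_Screening rows: {n} (screening.csv)_", ""]
    return "\n".join(lines)
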