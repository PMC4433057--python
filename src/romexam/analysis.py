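"""Study-level analysis and report rendering.

Glues the reliability layer to whole sheets: one stats dictionary per run
with, for every examination angle, the repetition-mean rating tables of both
sources (measurement and examiner), their ICC(3,k), the 3×3 Bland–Altman
agreement panel, the within-repetition repeatability and the validity flags
against the literature reference ranges.
"""

from __future__ import annotations

import math

import pandas as pd

from .catalog import Catalog
from .reliability import (
    BlandAltmanResult,
    ICCResult,
    agreement_panel,
    build_rating_table,
    icc_3k,
    repeatability_table,
    validity_flags,
)

__all__ = ["analyze_sheets", "render_report"]


def _check_keys(results: pd.DataFrame, examiner: pd.DataFrame) -> None:
    km = set(map(tuple, results[["subject", "rater", "angle_id"]].drop_duplicates().to_numpy()))
    ke = set(map(tuple, examiner[["subject", "rater", "angle_id"]].drop_duplicates().to_numpy()))
    orphans = km ^ ke
    if orphans:
        listing = ", ".join(str(o) for o in sorted(orphans, key=str)[:10])
        raise ValueError(
            f"results and examiner sheets disagree on {len(orphans)} "
            f"(subject, rater, angle) keys: {listing}"
        )


def _icc_dict(r: ICCResult) -> dict:
    return {
        "icc_3k": None if math.isnan(r.icc_3k) else r.icc_3k,
        "bms": r.bms,
        "jms": r.jms,
        "ems": r.ems,
        "n": r.n,
        "k": r.k,
        "acceptable": r.acceptable,
        "undefined": r.undefined,
    }


def _ba_dict(b: BlandAltmanResult) -> dict:
    return {
        "pair": list(b.rater_pair),
        "mdiff": b.mdiff,
        "sd_diff": b.sd_diff,
        "loa_low": b.loa_low,
        "loa_high": b.loa_high,
        "mdiff_acceptable": b.mdiff_acceptable,
        "n": int(len(b.points)),
    }


def analyze_sheets(
    results: pd.DataFrame, examiner: pd.DataFrame, catalog: Catalog
) -> tuple[dict, list[BlandAltmanResult]]:
    """Compute the full per-angle statistics of one study run.

    Returns the stats dictionary (JSON-serializable) and the flat list of all
    Bland–Altman comparisons (for plot-data export).  Angles appearing in
    only one sheet, or sheets with mismatched keys, are an error.
    """
    _check_keys(results, examiner)
    angle_ids = [a for a in catalog.angle_ids if a in set(results["angle_id"])]
    extra = set(results["angle_id"]) - set(catalog.angle_ids)
    if extra:
        raise KeyError(f"results sheet holds unknown examination angles: {sorted(extra)}")
    if not angle_ids:
        raise ValueError("results sheet holds no known examination angles")

    rep_by_family = repeatability_table(
        {
            "measurement": (results, "measured_rom_deg"),
            "examiner": (examiner, "rating_deg"),
        },
        catalog,
    )
    rep_by_angle = repeatability_table(
        {
            "measurement": (results, "measured_rom_deg"),
            "examiner": (examiner, "rating_deg"),
        }
    )

    stats: dict = {"angles": {}, "repeatability_by_family": rep_by_family.to_dict("records")}
    all_ba: list[BlandAltmanResult] = []
    for aid in angle_ids:
        mt = build_rating_table(results, aid, "measurement", "measured_rom_deg")
        et = build_rating_table(examiner, aid, "examiner", "rating_deg")
        panel = agreement_panel(mt, et)
        all_ba.extend(panel)
        mean_deg = float(mt.values.mean())
        vf = validity_flags({aid: mean_deg}, catalog).iloc[0]
        rep = {
            row["source"]: row["mean_sd_deg"]
            for _, row in rep_by_angle[rep_by_angle["angle_id"] == aid].iterrows()
        }
        stats["angles"][aid] = {
            "n": mt.n,
            "n_dropped": mt.n_dropped,
            "repeatability": rep,
            "icc": {
                "measurement": _icc_dict(icc_3k(mt)),
                "examiner": _icc_dict(icc_3k(et)),
            },
            "bland_altman": [_ba_dict(b) for b in panel],
            "validity": {
                "mean_deg": mean_deg,
                "flag_ref1": vf["flag_ref1"],
                "flag_ref2": vf["flag_ref2"],
            },
        }
    return stats, all_ba


def _fmt_icc(entry: dict) -> str:
    """Display rule: acceptable values bold, negative estimates floored to
    0.0 and flagged, undefined shown as 'n/a'."""
    v = entry["icc_3k"]
    if entry["undefined"] or v is None:
        return "n/a"
    flag = ""
    if v < 0:
        v, flag = 0.0, "†"
    s = f"{v:.2f}{flag}"
    return f"**{s}**" if entry["acceptable"] else s


def render_report(stats: dict) -> str:
    """Human-readable markdown summary with the acceptability rules applied
    (ICC ≥ 0.8 and |MDiff| < 5° printed bold)."""
    if not stats.get("angles"):
        raise ValueError("stats hold no angles to report")
    lines = ["# Examination study report", ""]

    lines += [
        "## Validity: cohort means vs reference ranges",
        "",
        "| Examination angle | Mean [°] | n | vs Reference1 | vs Reference2 |",
        "|---|---|---|---|---|",
    ]
    for aid, e in stats["angles"].items():
        v = e["validity"]
        lines.append(
            f"| {aid} | {v['mean_deg']:.1f} | {e['n']} | {v['flag_ref1']} | {v['flag_ref2']} |"
        )

    lines += [
        "",
        "## Repeatability: mean within-repetition SD [°]",
        "",
        "| Examination family | Measurements | Examiners |",
        "|---|---|---|",
    ]
    fam: dict[str, dict[str, float]] = {}
    for row in stats["repeatability_by_family"]:
        fam.setdefault(row["family"], {})[row["source"]] = row["mean_sd_deg"]
    for family, vals in fam.items():
        m = vals.get("measurement")
        x = vals.get("examiner")
        lines.append(
            f"| {family} | {'' if m is None else f'{m:.2f}'} | {'' if x is None else f'{x:.2f}'} |"
        )

    lines += [
        "",
        "## Inter-rater reliability: ICC(3,k)",
        "",
        "(† negative estimate floored to 0.0; bold = acceptable, ICC ≥ 0.8)",
        "",
        "| Examination angle | ICC (Measurements) | ICC (Examiners) |",
        "|---|---|---|",
    ]
    for aid, e in stats["angles"].items():
        lines.append(
            f"| {aid} | {_fmt_icc(e['icc']['measurement'])} | {_fmt_icc(e['icc']['examiner'])} |"
        )

    lines += [
        "",
        "## Inter-rater agreement: Bland–Altman",
        "",
        "(bold MDiff = acceptable systematic difference, |MDiff| < 5°)",
        "",
        "| Examination angle | Pair | MDiff [°] | LOA low [°] | LOA high [°] |",
        "|---|---|---|---|---|",
    ]
    for aid, e in stats["angles"].items():
        for b in e["bland_altman"]:
            md = f"{b['mdiff']:.1f}"
            if b["mdiff_acceptable"]:
                md = f"**{md}**"
            lines.append(
                f"| {aid} | {b['pair'][0]}-{b['pair'][1]} | {md} | "
                f"{b['loa_low']:.1f} | {b['loa_high']:.1f} |"
            )
    lines.append("")
    return "\n".join(lines)
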