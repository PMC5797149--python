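"""Human-readable study reports mirroring the standard table layouts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from telecg.rhythm import EpisodeCounts, group_summary


def hr_table_text(rows: list[dict]) -> str:
    """Minimal/maximal naturally occurring HR per group, mean +/- SEM."""
    df = pd.DataFrame(rows)
    lines = ["Heart rate under baseline conditions and under beta-adrenergic blockade",
             "(bpm, mean +/- SEM per group)", ""]
    for metric, label in (
        ("base_min", "baseline minimal HR"), ("base_max", "baseline maximal HR"),
        ("met_min", "metoprolol minimal HR"), ("met_max", "metoprolol maximal HR"),
        ("delta_day", "delta HR day"), ("delta_night", "delta HR night"),
    ):
        if metric not in df.columns:
            continue
        parts = []
        for strain, g in df.groupby("strain"):
            v = g[metric].dropna().to_numpy(float)
            if len(v) == 0:
                continue
            sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
            parts.append(f"{strain}: {v.mean():.0f} +/- {sem:.0f}")
        lines.append(f"{label:<24s} " + "   ".join(parts))
    return "\n".join(lines) + "\n"


def event_table_text(counts: dict[str, EpisodeCounts], strain_of: dict[str, str]) -> str:
    """Occurrence of ventricular arrhythmias per group and subclass:
    mean +/- SEM with the fraction of affected animals '(k/n)'."""
    df = group_summary(counts, strain_of)
    lines = ["Occurrence of ventricular arrhythmias under beta-adrenergic stimulation",
             "(events per animal over 5 h, mean +/- SEM; (affected/n))", ""]
    header = f"{'strain':<10s}" + "".join(f"{c:>22s}" for c in ("PVB", "Coupled beats", "VT", "VF", "Total"))
    lines.append(header)
    for strain in sorted(set(strain_of.values())):
        row = f"{strain:<10s}"
        for cls in ("pvb", "coupled", "vt", "vf", "total"):
            r = df[(df.strain == strain) & (df["class"] == cls)].iloc[0]
            row += f"{r['mean']:>10.1f} +/- {r['sem']:<4.1f}({r['n_affected']}/{r['n']})"
        lines.append(row)
    return "\n".join(lines) + "\n"
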