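"""Reproduction report: assembles run outputs into one markdown document.

The report gathers the summary tables written by the CLI subcommands from
an output directory, evaluates the qualitative ordering relations the
sensitivity analysis predicts (which stiffness combinations load which
tissue), includes the material cards verbatim for provenance, and appends
the mesh-convergence table when present.  Regeneration from the same
directory is idempotent.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import OntetherError

__all__ = ["ordering_checks", "build_report"]


def _pivot(df: pd.DataFrame, column: str) -> dict:
    out = {}
    for _, row in df.iterrows():
        out.setdefault(row["run"], {})[row["region"]] = row[column]
    return out


def ordering_checks(matrix_df: pd.DataFrame) -> pd.DataFrame:
    """Evaluate the sensitivity-matrix ordering relations.

    Each row is one predicted strict ordering: sheath-sclera junction
    stress larger with stiff than compliant posterior sclera (A>E, B>F,
    C>G, D>H); temporal ON-junction stress larger with compliant than
    stiff sheath (B>A, D>C, F>E, H>G); retrolaminar strain larger with
    compliant than stiff sheath; LC edge moving nasally and posteriorly in
    every tethering case.
    """
    stress = _pivot(matrix_df, "stress_kpa")
    strain = _pivot(matrix_df, "strain_pct")
    lc = {row["run"]: (row["lc_nasal_um"], row["lc_posterior_um"])
          for _, row in matrix_df.iterrows()}
    rows = []

    def add(name, hi, lo, table, region):
        if hi in table and lo in table:
            a, b = table[hi].get(region), table[lo].get(region)
            rows.append({"check": name, "value_hi": a, "value_lo": b,
                         "passed": bool(a > b)})

    for hi, lo in (("A", "E"), ("B", "F"), ("C", "G"), ("D", "H")):
        add(f"sheath junction stress {hi}>{lo}", hi, lo, stress,
            "sheath_sclera_junction")
    for hi, lo in (("B", "A"), ("D", "C"), ("F", "E"), ("H", "G")):
        add(f"ON junction stress {hi}>{lo}", hi, lo, stress,
            "on_junction_temporal")
        add(f"retrolaminar strain {hi}>{lo}", hi, lo, strain,
            "retrolaminar_neural")
    if "average" in stress:
        a = stress["average"]
        rows.append({"check": "temporal > nasal disc stress (average)",
                     "value_hi": a.get("on_junction_temporal"),
                     "value_lo": a.get("on_junction_nasal"),
                     "passed": bool(a.get("on_junction_temporal", 0)
                                    > a.get("on_junction_nasal", 0))})
    for run, (nas, post) in lc.items():
        rows.append({"check": f"LC edge nasal+posterior ({run})",
                     "value_hi": nas, "value_lo": post,
                     "passed": bool(nas > 0 and post > 0)})
    return pd.DataFrame(rows)


def build_report(output_dir, path=None) -> str:
    """Assemble the markdown report from a CLI output directory."""
    out = Path(output_dir)
    if not out.is_dir():
        raise OntetherError(f"output directory {out} does not exist")
    tables = sorted(out.glob("*summary*.csv"))
    if not tables:
        raise OntetherError(
            f"{out} contains no summary tables; run a scenario first")

    parts = ["# Optic-nerve tethering simulation report", ""]
    matrix_df = None
    for t in tables:
        df = pd.read_csv(t)
        parts += [f"## {t.name}", "", "```", df.to_string(index=False), "```", ""]
        if "matrix" in t.name:
            matrix_df = df
    if matrix_df is not None:
        checks = ordering_checks(matrix_df)
        parts += ["## Ordering checks", "", "```",
                  checks.to_string(index=False), "```", ""]
    conv = sorted(out.glob("*convergence*.csv"))
    for t in conv:
        parts += [f"## {t.name}", "", "```",
                  pd.read_csv(t).to_string(index=False), "```", ""]
    cards = resources.files("ontether").joinpath("data/material_cards.csv")
    parts += ["## Material cards (verbatim)", "", "```",
              cards.read_text(encoding="utf-8").strip(), "```", ""]
    text = "\n".join(parts)
    target = Path(path) if path else out / "report.md"
    target.write_text(text, encoding="utf-8")
    return text
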