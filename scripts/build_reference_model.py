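"""Regenerate the packaged illustrative POD reference network.

The DAG follows the published structure of the underlying chart-review
study's causal model; the interval tables are illustrative fixtures
produced by the qualitative rules below (tempered softmax scores and
narrative-consistent interval widths), NOT the study's elicited values,
which were never published.  Every table is labelled
``provenance: "illustrative"``.

Run from the repository root:

    python scripts/build_reference_model.py

Writes src/credalpod/data/pod-reference.json and
src/credalpod/data/network-schema.json, then validates the result.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "credalpod" / "data"

R = 3  # decimals in the shipped file


def binary_row(lo: float, hi: float) -> tuple[list[float], list[float]]:
    """Interval on the first state of a binary variable; complement on the second."""
    return [round(lo, R), round(1 - hi, R)], [round(hi, R), round(1 - lo, R)]


def one_free_row(point_probs: dict[int, float], free: int, comp: int,
                 lo: float, hi: float, k: int) -> tuple[list[float], list[float]]:
    """Row where all states are points except `free` (interval [lo, hi]) and
    `comp`, which absorbs the complement.  Two extreme points."""
    rest = round(sum(point_probs.values()), R)
    lo, hi = round(lo, R), round(hi, R)
    lower = [0.0] * k
    upper = [0.0] * k
    for i, p in point_probs.items():
        lower[i] = upper[i] = round(p, R)
    lower[free], upper[free] = lo, hi
    lower[comp] = round(1 - rest - hi, R)
    upper[comp] = round(1 - rest - lo, R)
    assert all(v >= 0 for v in lower), (point_probs, free, comp, lo, hi)
    return lower, upper


def softmax(scores: list[float]) -> list[float]:
    exps = [math.exp(s) for s in scores]
    z = sum(exps)
    return [e / z for e in exps]


variables = [
    ("cancer_treatment", ["ongoing", "discontinued"]),
    ("eol_communication", ["open", "delayed"]),
    ("patient_awareness", ["open", "closed", "not_assessed"]),
    ("family_awareness", ["open", "closed", "not_assessed"]),
    ("patient_preference", ["home", "hospital", "nursing_home", "not_assessed"]),
    ("symptom_burden", ["none_low", "medium", "high"]),
    ("hospital_days", ["low", "high"]),
    ("family_member_available", ["yes", "no"]),
    ("patient_dependence", ["low", "high"]),
    ("economic_resources", ["adequate", "limited"]),
    ("family_conditions", ["suitable", "unsuitable", "not_assessed"]),
    ("family_preference", ["home", "hospital", "nursing_home", "not_assessed"]),
    ("palliative_home_care", ["yes", "no"]),
    ("gp_home_visits", ["yes", "no"]),
    ("home_care_nurses", ["yes", "no"]),
    ("volunteers", ["involved", "not_involved"]),
    ("cost_coverage", ["yes", "no"]),
    ("home_care_network", ["strong", "weak"]),
    ("area_of_residence", ["rural", "urban"]),
    ("place_of_death", ["home", "hospital", "nursing_home"]),
]

arcs = {
    "eol_communication": ["cancer_treatment"],
    "patient_awareness": ["eol_communication"],
    "family_awareness": ["eol_communication"],
    "patient_preference": ["patient_awareness"],
    "hospital_days": ["symptom_burden", "cancer_treatment"],
    "family_conditions": [
        "family_member_available",
        "family_awareness",
        "patient_dependence",
        "symptom_burden",
        "economic_resources",
    ],
    "family_preference": ["family_conditions"],
    "home_care_network": [
        "palliative_home_care",
        "gp_home_visits",
        "home_care_nurses",
        "volunteers",
        "cost_coverage",
    ],
    "place_of_death": [
        "family_preference",
        "patient_preference",
        "hospital_days",
        "home_care_network",
        "area_of_residence",
    ],
}

tables: list[dict] = []


def add(variable: str, cfg: dict, lower, upper) -> None:
    # provenance comes from the file-level table_defaults
    tables.append(
        {"variable": variable, "parent_config": cfg, "lower": lower, "upper": upper}
    )


# Roots ---------------------------------------------------------------------
add("cancer_treatment", {}, *binary_row(0.53, 0.63))
add("symptom_burden", {}, [0.05, 0.26, 0.61], [0.05, 0.34, 0.69])
add("family_member_available", {}, *binary_row(0.60, 0.70))
add("patient_dependence", {}, *binary_row(0.30, 0.45))
add("economic_resources", {}, *binary_row(0.50, 0.70))
add("palliative_home_care", {}, *binary_row(0.25, 0.35))
add("gp_home_visits", {}, *binary_row(0.30, 0.40))
add("home_care_nurses", {}, *binary_row(0.75, 0.85))
add("volunteers", {}, *binary_row(0.55, 0.67))
add("cost_coverage", {}, *binary_row(0.50, 0.70))
add("area_of_residence", {}, *binary_row(0.24, 0.30))

# Treatment gates communication (ongoing treatment delays it) ---------------
add("eol_communication", {"cancer_treatment": "ongoing"}, *binary_row(0.20, 0.35))
add("eol_communication", {"cancer_treatment": "discontinued"}, *binary_row(0.60, 0.80))

# Awareness follows communication -------------------------------------------
for comm, (lo, hi), na in [("open", (0.60, 0.80), 0.01), ("delayed", (0.20, 0.30), 0.01)]:
    add("patient_awareness", {"eol_communication": comm},
        *one_free_row({2: na}, free=0, comp=1, lo=lo, hi=hi, k=3))
for comm, (lo, hi), na in [("open", (0.70, 0.85), 0.02), ("delayed", (0.30, 0.45), 0.02)]:
    add("family_awareness", {"eol_communication": comm},
        *one_free_row({2: na}, free=0, comp=1, lo=lo, hi=hi, k=3))

# Patient preference is mostly unassessed unless awareness is open ----------
add("patient_preference", {"patient_awareness": "open"},
    *one_free_row({2: 0.03, 3: 0.12}, free=0, comp=1, lo=0.45, hi=0.60, k=4))
add("patient_preference", {"patient_awareness": "closed"},
    *one_free_row({1: 0.12, 2: 0.05}, free=3, comp=0, lo=0.55, hi=0.70, k=4))
add("patient_preference", {"patient_awareness": "not_assessed"},
    *one_free_row({2: 0.0, 3: 0.92}, free=0, comp=1, lo=0.01, hi=0.05, k=4))

# Hospital days: symptom burden and ongoing treatment drive admissions ------
hd_low = {
    ("none_low", "ongoing"): (0.70, 0.85),
    ("none_low", "discontinued"): (0.85, 0.95),
    ("medium", "ongoing"): (0.45, 0.60),
    ("medium", "discontinued"): (0.60, 0.75),
    ("high", "ongoing"): (0.20, 0.35),
    ("high", "discontinued"): (0.35, 0.50),
}
for (sb, ct), (lo, hi) in hd_low.items():
    add("hospital_days", {"symptom_burden": sb, "cancer_treatment": ct},
        *binary_row(lo, hi))


# Family conditions for home care -------------------------------------------
def fc_suitable(fma: str, fa: str, dep: str, sb: str, er: str) -> tuple[float, float]:
    if fma == "no":
        # Without an available family member, only paid care can substitute.
        return (0.20, 0.40) if er == "adequate" else (0.05, 0.20)
    base = {"open": (0.80, 0.98), "closed": (0.50, 0.65),
            "not_assessed": (0.40, 0.55)}[fa]
    if sb == "high" or dep == "high":
        lo, hi = base
        return (max(0.05, lo - 0.40), max(0.15, hi - 0.42))
    return base


for fma in ["yes", "no"]:
    for fa in ["open", "closed", "not_assessed"]:
        for dep in ["low", "high"]:
            for sb in ["none_low", "medium", "high"]:
                for er in ["adequate", "limited"]:
                    lo, hi = fc_suitable(fma, fa, dep, sb, er)
                    add("family_conditions",
                        {"family_member_available": fma, "family_awareness": fa,
                         "patient_dependence": dep, "symptom_burden": sb,
                         "economic_resources": er},
                        *one_free_row({2: 0.02}, free=0, comp=1, lo=lo, hi=hi, k=3))

# Family preference follows the family's conditions -------------------------
add("family_preference", {"family_conditions": "suitable"},
    *one_free_row({2: 0.02, 3: 0.14}, free=0, comp=1, lo=0.48, hi=0.62, k=4))
add("family_preference", {"family_conditions": "unsuitable"},
    *one_free_row({0: 0.08, 2: 0.02}, free=3, comp=1, lo=0.28, hi=0.40, k=4))
add("family_preference", {"family_conditions": "not_assessed"},
    *one_free_row({2: 0.01, 3: 0.70}, free=0, comp=1, lo=0.08, hi=0.14, k=4))

# Home-care network: a near-deterministic tally of the five services --------
strong_by_score = {0: 0.02, 1: 0.10, 2: 0.25, 3: 0.45, 4: 0.65, 5: 0.82, 6: 0.93}
for phc in ["yes", "no"]:
    for gp in ["yes", "no"]:
        for hcn in ["yes", "no"]:
            for vol in ["involved", "not_involved"]:
                for cost in ["yes", "no"]:
                    score = (2 * (phc == "yes") + (gp == "yes") + (hcn == "yes")
                             + (vol == "involved") + (cost == "yes"))
                    p = strong_by_score[score]
                    add("home_care_network",
                        {"palliative_home_care": phc, "gp_home_visits": gp,
                         "home_care_nurses": hcn, "volunteers": vol,
                         "cost_coverage": cost},
                        [round(p, R), round(1 - p, R)],
                        [round(p, R), round(1 - p, R)])


# Place of death -------------------------------------------------------------
def pod_row(fp: str, pp: str, hd: str, hcn: str, area: str):
    home = 0.0
    home += {"home": 1.2, "hospital": -1.2, "nursing_home": -0.6,
             "not_assessed": -0.35}[fp]
    home += {"home": 0.35, "hospital": -0.35, "nursing_home": -0.15,
             "not_assessed": -0.10}[pp]
    home += 0.55 if hd == "low" else -0.55
    home += 0.50 if hcn == "strong" else -0.25
    home += 0.18 if area == "rural" else -0.07
    nh = -2.6 + (2.8 if fp == "nursing_home" else 0.0) + (1.6 if pp == "nursing_home" else 0.0)
    hosp = 0.75
    p_home, _, p_nh = softmax([home, hosp, nh])
    p_nh = round(p_nh, R)
    width = 0.07
    lo = round(min(max(p_home - width, 0.01), 1 - p_nh - 0.02), R)
    hi = round(min(p_home + width, 1 - p_nh - 0.01), R)
    lower = [lo, round(1 - p_nh - hi, R), p_nh]
    upper = [hi, round(1 - p_nh - lo, R), p_nh]
    return lower, upper


for fp in ["home", "hospital", "nursing_home", "not_assessed"]:
    for pp in ["home", "hospital", "nursing_home", "not_assessed"]:
        for hd in ["low", "high"]:
            for hcn in ["strong", "weak"]:
                for area in ["rural", "urban"]:
                    add("place_of_death",
                        {"family_preference": fp, "patient_preference": pp,
                         "hospital_days": hd, "home_care_network": hcn,
                         "area_of_residence": area},
                        *pod_row(fp, pp, hd, hcn, area))

network = {
    "name": "pod-reference",
    "description": (
        "Illustrative credal network over the determinants of cancer "
        "patients' place of death. Structure follows the expert-elicited "
        "causal model of the underlying chart-review study; all interval "
        "tables are illustrative stand-ins (the elicited values were never "
        "published) and are labelled provenance=illustrative."
    ),
    "table_defaults": {"provenance": "illustrative"},
    "variables": [{"name": n, "states": s} for n, s in variables],
    "arcs": [{"child": c, "parents": p} for c, p in arcs.items()],
    "tables": tables,
}


def main() -> None:
    out = DATA / "pod-reference.json"
    out.write_text(json.dumps(network, separators=(",", ":"), indent=None) + "\n")
    print(f"wrote {out} ({out.stat().st_size} bytes, {len(tables)} tables)")

    from credalpod.io import network_json_schema
    schema_path = DATA / "network-schema.json"
    schema_path.write_text(json.dumps(network_json_schema(), indent=1) + "\n")
    print(f"wrote {schema_path}")

    from credalpod.pod_model import load_reference_model
    model = load_reference_model()
    print(f"validated: {len(model.net.variables)} variables, "
          f"{len(model.net.tables)} tables")


if __name__ == "__main__":
    main()
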