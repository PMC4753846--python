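"""Presence/absence activity-pattern taxonomy across tissues and conditions.

Each gene's activity is summarized by the set of tissues in which it is
active under control and under water deficit.  Genes active in all four
tissues under both conditions are *constitutive*; genes active in the same
non-universal tissue set under both conditions are *stable* (single- or
multi-tissue); genes whose active-tissue set differs between conditions are
*dynamic* — a spatial *increase* when the deficit set strictly contains the
control set, a *decrease* when it is strictly contained, and a *change*
otherwise.  The number of activity-status changes is the size of the
symmetric difference of the two sets (0-4).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from rootzone.simulate import TISSUES

CATEGORIES = (
    "constitutive_all",
    "stable_single",
    "stable_multi",
    "dynamic_increase",
    "dynamic_decrease",
    "dynamic_change",
    "never_active",
)

_ALL = frozenset(TISSUES)


@dataclass(frozen=True)
class ActivityPattern:
    gene_id: str
    control_set: frozenset[str]
    deficit_set: frozenset[str]
    category: str
    n_changes: int


def _validate(tissues: frozenset[str]) -> None:
    bad = tissues - _ALL
    if bad:
        raise ValueError(f"unknown tissue label(s): {sorted(bad)}")


def count_changes(control_set, deficit_set) -> int:
    """Number of tissues whose activity status flips between conditions."""
    control_set, deficit_set = frozenset(control_set), frozenset(deficit_set)
    _validate(control_set)
    _validate(deficit_set)
    return len(control_set ^ deficit_set)


def classify_pattern(control_set, deficit_set, gene_id: str = "") -> ActivityPattern:
    """Assign a gene's (control, deficit) active-tissue sets to the taxonomy."""
    control_set, deficit_set = frozenset(control_set), frozenset(deficit_set)
    _validate(control_set)
    _validate(deficit_set)
    n = len(control_set ^ deficit_set)
    if control_set == deficit_set:
        if control_set == _ALL:
            category = "constitutive_all"
        elif not control_set:
            category = "never_active"
        elif len(control_set) == 1:
            category = "stable_single"
        else:
            category = "stable_multi"
    elif deficit_set > control_set:
        category = "dynamic_increase"
    elif deficit_set < control_set:
        category = "dynamic_decrease"
    else:
        category = "dynamic_change"
    return ActivityPattern(gene_id, control_set, deficit_set, category, n)


def patterns_from_calls(calls: pd.DataFrame) -> list[ActivityPattern]:
    """Classify every gene of an activity-call matrix (genes x 8 cell columns)."""
    out = []
    for gene, row in calls.iterrows():
        control = {t for t in TISSUES if row[f"{t}_control"]}
        deficit = {t for t in TISSUES if row[f"{t}_deficit"]}
        out.append(classify_pattern(control, deficit, gene_id=str(gene)))
    return out


def patterns_frame(patterns: list[ActivityPattern]) -> pd.DataFrame:
    """Per-gene pattern records as a tidy frame."""
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in patterns],
            "control_set": ["+".join(sorted(p.control_set)) for p in patterns],
            "deficit_set": ["+".join(sorted(p.deficit_set)) for p in patterns],
            "category": [p.category for p in patterns],
            "n_changes": [p.n_changes for p in patterns],
        }
    ).set_index("gene_id")


def tabulate_patterns(patterns: list[ActivityPattern]) -> dict[str, pd.Series]:
    """Summary tables over a gene population's activity patterns.

    Returns category counts, change-count distribution among dynamic genes,
    per-tissue active counts per condition, and the 4-way tissue-set (Venn)
    occupancy per condition.  ``never_active`` genes are excluded from the
    active-gene denominators reported in ``shares``.
    """
    frame = patterns_frame(patterns)
    category_counts = (
        frame["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    )
    dynamic = frame[frame["category"].str.startswith("dynamic")]
    change_counts = (
        dynamic["n_changes"].value_counts().reindex(range(1, 5), fill_value=0)
    )
    per_tissue = {}
    for cond, attr in (("control", "control_set"), ("deficit", "deficit_set")):
        for t in TISSUES:
            per_tissue[f"{t}_{cond}"] = int(
                frame[attr].str.contains(t).sum()
            )
    venn = {}
    subsets = [
        frozenset(c)
        for k in range(5)
        for c in combinations(TISSUES, k)
    ]
    for p in patterns:
        for cond, s in (("control", p.control_set), ("deficit", p.deficit_set)):
            key = f"{cond}:{'+'.join(sorted(s)) or '-'}"
            venn[key] = venn.get(key, 0) + 1
    for s in subsets:
        for cond in ("control", "deficit"):
            venn.setdefault(f"{cond}:{'+'.join(sorted(s)) or '-'}", 0)

    n_active = int(len(frame) - category_counts["never_active"])
    stable = int(category_counts["stable_single"] + category_counts["stable_multi"])
    dynamic_total = int(
        category_counts[["dynamic_increase", "dynamic_decrease",
                         "dynamic_change"]].sum()
    )
    shares = pd.Series(
        {
            "n_genes": len(frame),
            "n_active": n_active,
            "active_fraction": n_active / len(frame) if len(frame) else 0.0,
            "constitutive": int(category_counts["constitutive_all"]),
            "constitutive_share_of_active": (
                category_counts["constitutive_all"] / n_active if n_active else 0.0
            ),
            "stable_total": stable,
            "stable_single_share": (
                category_counts["stable_single"] / stable if stable else 0.0
            ),
            "dynamic_total": dynamic_total,
        }
    )
    return {
        "categories": category_counts,
        "changes": pd.Series(change_counts, name="n_dynamic_genes"),
        "per_tissue": pd.Series(per_tissue),
        "venn": pd.Series(venn).sort_index(),
        "shares": shares,
    }
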