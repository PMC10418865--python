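"""Metabolite-set over-representation analysis (hypergeometric ORA).

Given a selected metabolite list (here: metabolites chosen at least
``min_count`` times across all resampling rounds), a measured background and
named pathway sets, each pathway is scored by the upper-tail hypergeometric
probability P(X >= k) of its overlap with the selection, with
Benjamini-Hochberg adjustment across pathways.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .stability import IterationRecord
from .univariate import bh_adjust


def select_input_list(records: list[IterationRecord], min_count: int = 3) -> list[str]:
    """Metabolites selected in at least ``min_count`` rounds (all rounds,
    before any AUC-based exclusion), deduplicated and sorted."""
    counts: dict[str, int] = {}
    for r in records:
        for f in r.selected:
            counts[f] = counts.get(f, 0) + 1
    return sorted(f for f, c in counts.items() if c >= min_count)


def ora(
    selected: list[str],
    background: list[str],
    pathways: dict[str, list[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per pathway.

    Pathways are intersected with the background before testing; K is the
    pathway size within the background (N), n the selection size, k the
    overlap, and p = P(X >= k) under sampling n of N without replacement.
    Rows are sorted by p; ``q`` is the BH adjustment across pathways.
    """
    bg = set(background)
    sel = set(selected)
    offenders = sorted(sel - bg)
    if offenders:
        raise ValueError(f"selected metabolites not in background: {offenders}")
    N, n = len(bg), len(sel)
    rows = []
    for name, members in pathways.items():
        in_bg = sorted(set(members) & bg)
        K = len(in_bg)
        overlap = sorted(set(in_bg) & sel)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "pathway": name,
                "pathway_size": K,
                "selected_size": n,
                "overlap": k,
                "p": min(p, 1.0),
                "members": ";".join(overlap),
            }
        )
    table = pd.DataFrame(rows).set_index("pathway")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values("p", kind="mergesort")


def demo_pathways() -> dict[str, list[str]]:
    """A small built-in pathway library covering the arginine-related
    pathways this package's application domain highlights.  Users supply
    their own library (JSON: name -> metabolite ids) for real analyses."""
    return {
        "arginine and proline metabolism": [
            "Arg", "Orn", "Cit", "Pro", "t4-OH-Pro", "Glu", "Gln", "Putrescine",
            "Spermidine", "Spermine", "Creatine",
        ],
        "arginine biosynthesis": ["Arg", "Orn", "Cit", "Asn", "Asp", "Glu", "Gln"],
        "glycine, serine and threonine metabolism": [
            "Gly", "Ser", "Thr", "Betaine", "Sarcosine", "Creatine",
        ],
        "lysine degradation": ["Lys", "5-AVA", "Carnitine"],
        "sphingolipid metabolism": [
            "SM_001", "SM_002", "Cer_001", "Cer_002", "HexCer_001", "Hex2Cer_001",
        ],
    }


def load_pathways(path) -> dict[str, list[str]]:
    return {str(k): list(v) for k, v in json.loads(Path(path).read_text()).items()}


def save_pathways(pathways: dict[str, list[str]], path) -> None:
    Path(path).write_text(json.dumps(pathways, indent=1))
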