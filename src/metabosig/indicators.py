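"""Named sums and ratios of metabolites used as metabolic-process indicators.

Targeted kits ship hundreds of such indicators; this module implements the
handful with a published physiological reading that this package's
application domain relies on — arginine/NO metabolism (Pro/Cit, Cit/Arg,
GABR), sphingolipid turnover (SM/PC, Hex2Cer/Cer, Hex2Cer/HexCer), one-carbon
metabolism (Gly/Ser) and the strictly ketogenic amino-acid sum (Lys + Leu).
Definitions are plain data and user-extensible via JSON.

A definition term of the form ``class:SM`` expands to every catalogued
metabolite of that chemical class at evaluation time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .quant import QuantMatrix
from .simulate import MetaboliteCatalog

log = logging.getLogger(__name__)


@dataclasses.dataclass
class IndicatorDefinition:
    """A ratio (or pure sum, when ``denominator`` is empty) of summed
    metabolite concentrations."""

    name: str
    numerator: list[str]
    denominator: list[str] = dataclasses.field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if not self.numerator:
            raise ValueError(f"indicator {self.name!r}: numerator must be non-empty")
        overlap = set(self.numerator) & set(self.denominator)
        if overlap:
            raise ValueError(
                f"indicator {self.name!r}: terms {sorted(overlap)} appear on both sides"
            )


def builtin_catalog() -> list[IndicatorDefinition]:
    """The built-in indicator definitions."""
    return [
        IndicatorDefinition(
            "arginase_vs_NOS",
            ["Pro"],
            ["Cit"],
            "Pro/Cit: relative arginase activity compared to NO synthase",
        ),
        IndicatorDefinition(
            "NOS_activity",
            ["Cit"],
            ["Arg"],
            "Cit/Arg: nitric-oxide-synthase activity",
        ),
        IndicatorDefinition(
            "GABR",
            ["Arg"],
            ["Orn", "Cit"],
            "global arginine bioavailability ratio Arg/(Orn+Cit)",
        ),
        IndicatorDefinition(
            "SM_to_PC",
            ["class:SM"],
            ["class:PC"],
            "sphingomyelin synthase activity: total SM over total PC",
        ),
        IndicatorDefinition(
            "Hex2Cer_to_Cer",
            ["class:Hex2Cer"],
            ["class:Cer"],
            "dihexosylceramides over ceramides",
        ),
        IndicatorDefinition(
            "Hex2Cer_to_HexCer",
            ["class:Hex2Cer"],
            ["class:HexCer"],
            "dihexosylceramides relative to the hexosylceramide pool",
        ),
        IndicatorDefinition(
            "glycine_synthesis",
            ["Gly"],
            ["Ser"],
            "glycine synthesis ratio (SHMT activity): Gly/Ser",
        ),
        IndicatorDefinition(
            "ketogenic_AAs",
            ["Lys", "Leu"],
            [],
            "sum of the strictly ketogenic amino acids",
        ),
    ]


def save_definitions(defs: list[IndicatorDefinition], path) -> None:
    Path(path).write_text(
        json.dumps([dataclasses.asdict(d) for d in defs], indent=1)
    )


def load_definitions(path) -> list[IndicatorDefinition]:
    return [IndicatorDefinition(**d) for d in json.loads(Path(path).read_text())]


def _expand(terms: list[str], catalog: MetaboliteCatalog | None) -> list[str]:
    out: list[str] = []
    for t in terms:
        if t.startswith("class:"):
            if catalog is None:
                raise ValueError(f"term {t!r} needs a metabolite catalogue")
            out.extend(catalog.members(t.split(":", 1)[1]))
        else:
            out.append(t)
    return out


def evaluate(
    matrix: QuantMatrix,
    defs: list[IndicatorDefinition] | None = None,
    catalog: MetaboliteCatalog | None = None,
) -> pd.DataFrame:
    """Per-sample indicator values, one column per evaluable definition.

    An indicator referencing metabolites absent from the matrix is skipped
    with a logged warning; a zero denominator yields NaN for that sample (the
    value is flagged undefined, never silently dropped).
    """
    if defs is None:
        defs = builtin_catalog()
    present = set(matrix.metabolites)
    out = {}
    for d in defs:
        try:
            num = _expand(d.numerator, catalog)
            den = _expand(d.denominator, catalog)
        except ValueError as exc:
            log.warning("skipping indicator %s: %s", d.name, exc)
            continue
        missing = [m for m in num + den if m not in present]
        if missing or not num:
            log.warning(
                "skipping indicator %s: metabolites not measured: %s", d.name, missing
            )
            continue
        numerator = matrix.values[num].sum(axis=1)
        if den:
            denominator = matrix.values[den].sum(axis=1)
            vals = numerator / denominator.replace(0.0, np.nan)
        else:
            vals = numerator
        out[d.name] = vals
    return pd.DataFrame(out, index=matrix.values.index)
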