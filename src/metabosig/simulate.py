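"""Synthetic two-group targeted-metabolomics data with known ground truth.

The generator emulates the statistical structure of a Biocrates-style
quantification matrix from a two-arm animal experiment (sham vs stroke):

* lognormal concentrations with strong intra-class correlation, produced by a
  latent one-factor-per-class model on the log scale;
* a configurable number of informative metabolites whose log concentrations
  differ between groups by a chosen standardized effect size (Cohen's d on the
  log scale);
* limit-of-quantification censoring, with LLOQ set at a quantile of each
  metabolite's marginal distribution so a target out-of-LOQ fraction is hit,
  optionally associated with the group label (a metabolite quantifiable in one
  group only);
* whole-profile multiplicative outlier samples, the kind a PCA screen should
  flag.

Defaults follow the study design this package targets: 28 sham and 12 stroke
samples, a ~400-metabolite plasma panel and a ~154-metabolite heart panel.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .quant import QuantMatrix, derive_status

#: canonical amino-acid style names used for the "AA" class so the built-in
#: indicator ratios (Pro/Cit, Cit/Arg, GABR, Gly/Ser, ...) resolve on
#: synthetic data.
AMINO_ACID_NAMES = (
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp",
    "t4-OH-Pro", "Tyr", "Val", "Betaine", "5-AVA", "Taurine", "Sarcosine",
)


@dataclasses.dataclass
class BlockSpec:
    """One chemical-class correlation block: label, size, intra-block rho."""

    name: str
    size: int
    rho: float


@dataclasses.dataclass
class CensorRule:
    """Target out-of-LOQ fraction applied to ``n_metabolites`` metabolites.

    ``class_associated`` plants a strong group shift on the affected
    metabolites so censoring concentrates in one group (the situation the
    chi-squared rescue of the LOQ filter is designed to keep).
    """

    fraction: float
    n_metabolites: int
    class_associated: bool = False


def _default_plasma_blocks() -> list[BlockSpec]:
    return [
        BlockSpec("PC", 80, 0.5),
        BlockSpec("lysoPC", 14, 0.5),
        BlockSpec("SM", 15, 0.6),
        BlockSpec("Cer", 28, 0.6),
        BlockSpec("HexCer", 19, 0.6),
        BlockSpec("Hex2Cer", 9, 0.6),
        BlockSpec("TG", 120, 0.7),
        BlockSpec("AA", 26, 0.3),
        BlockSpec("BA", 8, 0.4),
        BlockSpec("other", 81, 0.2),
    ]


def _default_heart_blocks() -> list[BlockSpec]:
    return [
        BlockSpec("PC", 40, 0.5),
        BlockSpec("SM", 8, 0.6),
        BlockSpec("Cer", 12, 0.6),
        BlockSpec("AA", 26, 0.3),
        BlockSpec("BA", 6, 0.4),
        BlockSpec("other", 62, 0.2),
    ]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one simulated two-group dataset.

    Defaults emulate the plasma arm of the targeted study design: 28 sham vs
    12 stroke samples, 420 assayed metabolites of which ~400 survive the LOQ
    filter, 20 informative metabolites with standardized log-scale effect
    sizes spread over 0.4-1.8.
    """

    n_group_a: int = 28              # sham
    n_group_b: int = 12              # stroke
    n_metabolites: int = 420
    n_informative: int = 20
    effect_sizes: tuple[float, ...] | None = None   # |d| on the log scale
    blocks: list[BlockSpec] | None = None
    base_censor_fraction: float = 0.05
    censor_rules: tuple[CensorRule, ...] = (
        CensorRule(0.45, 20, class_associated=False),
        CensorRule(0.40, 2, class_associated=True),
    )
    class_censor_shift: float = 3.0  # |d| planted on class-censored metabolites
    n_outliers: int = 0
    outlier_scale: float = 10.0
    tissue: str = "plasma"
    group_labels: tuple[str, str] = ("sham", "stroke")
    log_mean_range: tuple[float, float] = (math.log(0.05), math.log(500.0))
    log_sd_range: tuple[float, float] = (0.25, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blocks is None:
            base = (
                _default_heart_blocks()
                if self.tissue == "heart"
                else _default_plasma_blocks()
            )
            total = sum(b.size for b in base)
            if total <= self.n_metabolites:
                self.blocks = base
            else:
                # scale the default panel down proportionally
                scale = self.n_metabolites / total
                self.blocks = [
                    BlockSpec(b.name, int(b.size * scale), b.rho)
                    for b in base
                    if int(b.size * scale) > 0
                ]
        if self.effect_sizes is None:
            if self.n_informative > 1:
                self.effect_sizes = tuple(
                    np.round(np.linspace(0.4, 1.8, self.n_informative), 3)
                )
            else:
                self.effect_sizes = (1.0,) * self.n_informative
        self.validate()

    def validate(self) -> None:
        for field in ("n_group_a", "n_group_b", "n_metabolites"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")
        if not 0 <= self.n_informative <= self.n_metabolites:
            raise ValueError("n_informative must lie in [0, n_metabolites]")
        if len(self.effect_sizes) < self.n_informative:
            raise ValueError("effect_sizes shorter than n_informative")
        if not all(np.isfinite(self.effect_sizes)):
            raise ValueError("effect_sizes must be finite")
        for b in self.blocks:
            if not 0 <= b.rho < 1:
                raise ValueError(f"blocks: correlation for {b.name!r} not in [0,1)")
            if b.size < 0:
                raise ValueError(f"blocks: negative size for {b.name!r}")
        if sum(b.size for b in self.blocks) > self.n_metabolites:
            raise ValueError("blocks: sizes sum beyond n_metabolites")
        for rule in self.censor_rules:
            if not 0 <= rule.fraction <= 1:
                raise ValueError("censor_rules: fraction must lie in [0,1]")
        if not 0 <= self.base_censor_fraction <= 1:
            raise ValueError("base_censor_fraction must lie in [0,1]")
        if self.n_outliers < 0 or self.n_outliers > self.n_group_a + self.n_group_b:
            raise ValueError("n_outliers out of range")
        if self.n_outliers and self.outlier_scale <= 1:
            raise ValueError("outlier_scale must be > 1")

    @property
    def n_samples(self) -> int:
        return self.n_group_a + self.n_group_b


def plasma_config(**overrides) -> SimulationConfig:
    """The default plasma-arm design (28/12 samples, ~400-metabolite panel)."""
    return SimulationConfig(**overrides)


def heart_config(**overrides) -> SimulationConfig:
    """Heart-arm design: 40 tissue samples with weights, ~154-metabolite
    panel, one planted whole-profile outlier (so 39 samples survive the PCA
    screen)."""
    defaults = dict(
        n_metabolites=160,
        n_informative=7,
        tissue="heart",
        n_outliers=1,
        censor_rules=(CensorRule(0.45, 6, class_associated=False),),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def recovery_config(
    n_metabolites: int = 200,
    n_informative: int = 10,
    effect_size: float = 1.3,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Signal-recovery benchmark fixture: 28/12 samples, independent
    metabolites (no correlation blocks), ``n_informative`` planted effects of
    a single standardized size, negligible censoring.

    Independence keeps recall/precision against the planted set well defined:
    with correlated blocks, neighbours of an informative metabolite carry
    genuine signal and an all-relevant selector is *right* to pick them.
    """
    defaults = dict(
        n_metabolites=n_metabolites,
        n_informative=n_informative,
        effect_sizes=(effect_size,) * n_informative,
        blocks=[BlockSpec("met", n_metabolites, 0.0)],
        censor_rules=(),
        base_censor_fraction=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def null_config(n_metabolites: int = 200, seed: int = 0, **overrides) -> SimulationConfig:
    """Matched no-signal fixture: identical shape, zero informative
    metabolites, exchangeable group labels."""
    return recovery_config(
        n_metabolites=n_metabolites, n_informative=0, seed=seed, **overrides
    )


@dataclasses.dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    informative_metabolite_ids: list[str]
    log_shifts: dict[str, float]          # signed shift of group-b log mean
    outlier_sample_ids: list[str]
    censored_fractions: dict[str, float]  # targets, by metabolite
    class_censored_ids: list[str]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclasses.dataclass
class MetaboliteCatalog:
    """Chemical-class labels and pathway memberships for a metabolite panel."""

    classes: dict[str, str]               # metabolite id -> class label
    pathways: dict[str, list[str]]        # pathway name -> metabolite ids

    def members(self, class_label: str) -> list[str]:
        return [m for m, c in self.classes.items() if c == class_label]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"classes": self.classes, "pathways": self.pathways}, indent=1)
        )

    @classmethod
    def from_json(cls, path) -> "MetaboliteCatalog":
        data = json.loads(Path(path).read_text())
        return cls(classes=data["classes"], pathways=data["pathways"])


# ---------------------------------------------------------------------------
# deterministic planning shared by generate_matrix and generate_catalog

def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Per-stage child generators derived from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _plan(config: SimulationConfig):
    """Deterministic layout: metabolite names, classes, informative set, shifts.

    Both :func:`generate_matrix` and :func:`generate_catalog` derive from this
    plan, so the catalogue's pathways agree with the matrix's planted signal.
    """
    rng_plan, rng_values, rng_catalog = _child_rngs(config.seed, 3)

    names: list[str] = []
    classes: dict[str, str] = {}
    block_of: list[int] = []
    aa_cursor = 0
    for bi, block in enumerate(config.blocks):
        for j in range(block.size):
            if block.name == "AA" and aa_cursor < len(AMINO_ACID_NAMES):
                name = AMINO_ACID_NAMES[aa_cursor]
                aa_cursor += 1
            else:
                name = f"{block.name}_{j + 1:03d}"
            names.append(name)
            classes[name] = block.name
            block_of.append(bi)
    extra = config.n_metabolites - len(names)
    for j in range(extra):
        name = f"unassigned_{j + 1:03d}"
        names.append(name)
        classes[name] = "unassigned"
        block_of.append(-1)

    n_m = config.n_metabolites
    mu = rng_plan.uniform(*config.log_mean_range, size=n_m)
    sigma = rng_plan.uniform(*config.log_sd_range, size=n_m)

    informative_idx = (
        rng_plan.choice(n_m, size=config.n_informative, replace=False)
        if config.n_informative
        else np.array([], dtype=int)
    )
    signs = rng_plan.choice([-1.0, 1.0], size=config.n_informative)
    d_sizes = np.asarray(config.effect_sizes[: config.n_informative], dtype=float)

    # censoring targets
    censor_target = np.full(n_m, config.base_censor_fraction)
    informative_set = set(informative_idx.tolist())
    free = [i for i in range(n_m) if i not in informative_set]
    rng_plan.shuffle(free)
    cursor = 0
    class_censored_idx: list[int] = []
    for rule in config.censor_rules:
        take = free[cursor : cursor + rule.n_metabolites]
        cursor += rule.n_metabolites
        for i in take:
            censor_target[i] = rule.fraction
            if rule.class_associated:
                class_censored_idx.append(i)

    # signed log-scale shifts (group b minus group a), in SD units times sigma
    shifts = np.zeros(n_m)
    shifts[informative_idx] = signs * d_sizes * sigma[informative_idx]
    # class-censored metabolites carry a strong downward shift in group b so
    # their below-LLOQ values concentrate in that group
    for i in class_censored_idx:
        shifts[i] = -config.class_censor_shift * sigma[i]

    all_informative_idx = np.concatenate(
        [informative_idx, np.array(class_censored_idx, dtype=int)]
    ).astype(int)

    return {
        "names": names,
        "classes": classes,
        "block_of": np.array(block_of),
        "mu": mu,
        "sigma": sigma,
        "shifts": shifts,
        "informative_idx": all_informative_idx,
        "planted_idx": informative_idx,
        "class_censored_idx": np.array(class_censored_idx, dtype=int),
        "censor_target": censor_target,
        "rng_values": rng_values,
        "rng_catalog": rng_catalog,
    }


# ---------------------------------------------------------------------------

def generate_matrix(config: SimulationConfig) -> tuple[QuantMatrix, GroundTruth]:
    """Draw one dataset under ``config``.

    Log concentrations follow a one-factor-per-class latent model:
    ``log x = mu_m + sigma_m * (sqrt(rho) F_class + sqrt(1-rho) eps) + shift_m * [group b]``
    with ``shift_m = d_m * sigma_m``, so informative metabolites differ by the
    configured Cohen's d on the log scale.  LLOQ is the per-metabolite
    empirical quantile hitting the censoring target; ULOQ sits above the
    observed maximum (upper censoring is left to explicit configurations).
    Identical config and seed give bit-identical output.
    """
    config.validate()
    plan = _plan(config)
    rng = plan["rng_values"]
    n, n_m = config.n_samples, config.n_metabolites
    n_a = config.n_group_a

    group = np.array([0] * n_a + [1] * config.n_group_b)
    n_blocks = len(config.blocks)
    factors = rng.standard_normal((n, n_blocks + 1))  # last column for unassigned
    eps = rng.standard_normal((n, n_m))

    rho = np.zeros(n_m)
    for i, bi in enumerate(plan["block_of"]):
        rho[i] = config.blocks[bi].rho if bi >= 0 else 0.0
    fcol = np.where(plan["block_of"] >= 0, plan["block_of"], n_blocks)

    z = np.sqrt(rho)[None, :] * factors[:, fcol] + np.sqrt(1 - rho)[None, :] * eps
    log_x = (
        plan["mu"][None, :]
        + plan["sigma"][None, :] * z
        + plan["shifts"][None, :] * group[:, None]
    )
    values = np.exp(log_x)

    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    labels = np.where(group == 0, config.group_labels[0], config.group_labels[1])

    # outliers: whole-profile multiplicative scaling of randomly chosen samples
    outlier_pos = (
        sorted(rng.choice(n, size=config.n_outliers, replace=False).tolist())
        if config.n_outliers
        else []
    )
    for pos in outlier_pos:
        values[pos, :] *= config.outlier_scale

    # LOQ bounds from marginal quantiles (outliers excluded from the quantile
    # so a scaled profile does not move the bounds)
    core = np.ones(n, dtype=bool)
    core[outlier_pos] = False
    lloq = np.empty(n_m)
    uloq = np.empty(n_m)
    for j in range(n_m):
        f = plan["censor_target"][j]
        col = values[core, j]
        lloq[j] = np.quantile(col, f) if f > 0 else col.min() / 2.0
        uloq[j] = col.max() * 2.0

    weights = (
        np.round(rng.uniform(80.0, 120.0, size=n), 2)
        if config.tissue == "heart"
        else np.full(n, np.nan)
    )
    samples = pd.DataFrame(
        {"group": labels, "tissue": config.tissue, "weight_mg": weights},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values_df = pd.DataFrame(
        values, index=samples.index, columns=pd.Index(plan["names"], name=None)
    )
    loq_df = pd.DataFrame(
        {"lloq": lloq, "uloq": uloq}, index=pd.Index(plan["names"], name="metabolite_id")
    )
    matrix = QuantMatrix(
        values=values_df,
        loq=loq_df,
        samples=samples,
        status=derive_status(values_df, loq_df),
    )

    names = plan["names"]
    informative_ids = [names[i] for i in plan["informative_idx"]]
    truth = GroundTruth(
        informative_metabolite_ids=informative_ids,
        log_shifts={names[i]: float(plan["shifts"][i]) for i in range(n_m)},
        outlier_sample_ids=[sample_ids[i] for i in outlier_pos],
        censored_fractions={
            names[i]: float(plan["censor_target"][i]) for i in range(n_m)
        },
        class_censored_ids=[names[i] for i in plan["class_censored_idx"]],
    )
    return matrix, truth


def generate_catalog(config: SimulationConfig) -> MetaboliteCatalog:
    """Chemical classes and pathway sets matching :func:`generate_matrix`.

    Besides random pathways, the catalogue carries two amino-acid pathways
    named after the arginine pathways relevant to the application domain and a
    synthetic ``planted_response`` pathway built to overlap the informative
    set (~80% of it), which downstream over-representation analysis should
    recover.
    """
    plan = _plan(config)
    rng = plan["rng_catalog"]
    names = plan["names"]
    classes = plan["classes"]

    pathways: dict[str, list[str]] = {}
    present = set(names)
    arg_pro = [m for m in ("Arg", "Orn", "Cit", "Pro", "t4-OH-Pro", "Glu", "Gln") if m in present]
    arg_bio = [m for m in ("Arg", "Orn", "Cit", "Asn", "Glu", "Gln", "Asp") if m in present]
    if arg_pro:
        pathways["arginine and proline metabolism"] = arg_pro
    if arg_bio:
        pathways["arginine biosynthesis"] = arg_bio

    informative = [names[i] for i in plan["planted_idx"]]
    if informative:
        k = max(1, math.ceil(0.8 * len(informative)))
        chosen = [informative[i] for i in rng.choice(len(informative), size=k, replace=False)]
        others = [m for m in names if m not in set(chosen)]
        extra = [others[i] for i in rng.choice(len(others), size=min(4, len(others)), replace=False)]
        pathways["planted_response"] = sorted(chosen + extra)

    for p in range(6):
        size = int(rng.integers(8, 26))
        members = [names[i] for i in rng.choice(len(names), size=size, replace=False)]
        pathways[f"random_pathway_{p + 1}"] = sorted(members)

    return MetaboliteCatalog(classes=classes, pathways=pathways)
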