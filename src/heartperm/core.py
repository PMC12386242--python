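"""Scoring and permutation inference for cardiac cell-division defects in the
Drosophila embryonic heart tube.

The stage-16 Drosophila dorsal vessel is built from bilaterally paired
hemisegments along abdominal segments A2–A8 (14 hemisegments per embryo).
Each wild-type hemisegment carries 2 Svp cardiac cells (CCs), 2 Svp
pericardial cells (PCs) and 4 Tin CCs, produced by stereotyped progenitor
divisions: the Tin superprogenitor divides symmetrically twice (1 → 4 CCs),
while the Svp superprogenitor divides symmetrically once and each daughter
then divides asymmetrically into one CC and one PC (1 → 2 CC + 2 PC).
Deviations from the expected cell census therefore pinpoint which division
failed, and hemisegment count tables scored from confocal z-stacks can be
classified into three defect categories:

* ``tin_symmetric``   — any Tin CC count other than 4;
* ``svp_earlier``     — earlier symmetric superprogenitor defect, census
  (svp_cc, svp_pc) in {(1,1), (3,3)};
* ``svp_asymmetric``  — asymmetric progenitor defect, census in
  {(1,3), (3,1)} or the karyokinesis signature (2,1) (one enlarged CC
  nucleus instead of a CC/PC pair).

Two assay modes exist: the *svp-lacZ* enhancer-trap reporter shows both Svp
CCs and Svp PCs (all three categories scorable), while the anti-Svp antibody
shows only Svp CCs, collapsing the two Svp categories into a single combined
flag (``svp_combined`` := svp_cc != 2).

Statistics: hemisegments within one embryo are correlated in their defect
propensity, so hemisegment-level contingency tests (e.g. Fisher's exact) are
invalid. Inference instead treats the per-embryo defect *proportion* Y_j as
the unit of analysis and uses permutation (randomization) tests on linear
models:

* two-group model      Y_j = b0 + b1·I_j + e_j, permuting genotype labels
  across embryos;
* interaction model    Y_j = b1·Ip_j + b2·Iq_j + b3·Ip_j·Iq_j + e_j (no
  intercept, fit on the two single-heterozygote groups and the double
  heterozygote), where b3 = mean(double) − mean(singleP) − mean(singleQ)
  measures departure from the additive expectation; H0: b3 = 0 is tested by
  the Smith procedure — orthogonalize the interaction column against the
  main-effect columns and permute the orthogonalized regressor.

Permutation p-values use p = (n+1)/(N+1), n = number of permuted statistics
exceeding the observed one out of N permutations; small samples switch to
exhaustive enumeration of all distinct arrangements.

The module is laid out in pipeline order:

1. constants & logging
2. phenotype scoring (records → defect calls → embryo summaries → tables)
3. synthetic cohorts (logit-normal clustered defect generator)
4. permutation inference (two-group, Smith interaction, simulation harness)
5. pipeline (CSV IO, report tables, orchestration)
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace, asdict
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

__all__ = [
    # constants
    "SEGMENTS", "SIDES", "SVP_LACZ", "SVP_ANTIBODY",
    "TIN_SYMMETRIC", "SVP_EARLIER", "SVP_ASYMMETRIC", "SVP_COMBINED",
    "UNCLASSIFIED_SVP", "CATEGORIES_LACZ", "CATEGORIES_ANTIBODY",
    "default_segments", "categories_for_assay",
    # phenotype scoring
    "CellCountRecord", "DefectCall", "EmbryoSummary",
    "simulate_symmetric_divisions", "simulate_svp_lineage",
    "wildtype_census",
    "classify_hemisegment", "classify_table",
    "summarize_embryo", "summarize_table", "aggregate_genotype",
    # synthetic cohorts
    "GeneratorConfig", "SyntheticCohort", "draw_defect_flags",
    "latent_rate_for_marginal",
    "sample_embryo", "generate_cohort", "generator_config_from_yaml",
    # permutation inference
    "ProportionSample", "PermutationConfig", "PermutationResult",
    "ols_fit", "pvalue_from_exceedances", "two_group_perm_test",
    "smith_orthogonalize", "interaction_perm_test", "synergy_call",
    "simulation_study", "interaction_scenarios", "two_group_null_scenario",
    # pipeline
    "RunConfig", "read_counts", "write_counts", "records_to_frame",
    "frame_to_records", "run_pipeline", "format_percent", "format_pvalue",
]

logger = logging.getLogger("heartperm")


def configure_logging(level: str = "INFO") -> None:
    """Attach a basic stderr handler to the package logger (idempotent)."""
    logger.setLevel(level.upper())
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(h)


# ---------------------------------------------------------------------------
# 1. Constants
# ---------------------------------------------------------------------------

SEGMENTS = ("A2", "A3", "A4", "A5", "A6", "A7", "A8")
SIDES = ("L", "R")

SVP_LACZ = "SVP_LACZ"          # svp-lacZ reporter: Svp CCs and PCs visible
SVP_ANTIBODY = "SVP_ANTIBODY"  # anti-Svp antibody: Svp PCs not visible
ASSAYS = (SVP_LACZ, SVP_ANTIBODY)

TIN_SYMMETRIC = "tin_symmetric"
SVP_EARLIER = "svp_earlier"
SVP_ASYMMETRIC = "svp_asymmetric"
SVP_COMBINED = "svp_combined"
UNCLASSIFIED_SVP = "unclassified_svp"

CATEGORIES_LACZ = (TIN_SYMMETRIC, SVP_EARLIER, SVP_ASYMMETRIC)
CATEGORIES_ANTIBODY = (TIN_SYMMETRIC, SVP_COMBINED)

# (svp_cc, svp_pc) census signatures in svp-lacZ mode
EARLIER_PATTERNS = ((1, 1), (3, 3))
ASYMMETRIC_PATTERNS = ((1, 3), (3, 1), (2, 1))
KARYOKINESIS_PATTERN = (2, 1)   # one enlarged CC nucleus, arrested division
NORMAL_SVP_PATTERN = (2, 2)

EXPECTED_TIN_CC = 4

COUNT_COLUMNS = (
    "embryo_id", "genotype", "segment", "side",
    "tin_cc", "svp_cc", "svp_pc", "enlarged_svp_nucleus", "assay",
)


def default_segments() -> tuple[tuple[str, str], ...]:
    """A2–A8 scored bilaterally: the 14 hemisegments of one embryo."""
    return tuple((seg, side) for seg in SEGMENTS for side in SIDES)


def categories_for_assay(assay: str) -> tuple[str, ...]:
    if assay == SVP_LACZ:
        return CATEGORIES_LACZ
    if assay == SVP_ANTIBODY:
        return CATEGORIES_ANTIBODY
    raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")


# ---------------------------------------------------------------------------
# 2. Phenotype scoring
# ---------------------------------------------------------------------------

def simulate_symmetric_divisions(n_rounds: int, n_cells: int = 1) -> int:
    """Cell census after ``n_rounds`` of error-free symmetric division.

    The Tin superprogenitor undergoes two such rounds, 1 → 4 Tin CCs.
    """
    if n_rounds < 0:
        raise ValueError("n_rounds must be non-negative")
    cells = n_cells
    for _ in range(n_rounds):
        cells *= 2
    return cells


def simulate_svp_lineage() -> tuple[int, int]:
    """(svp_cc, svp_pc) census of an error-free Svp lineage.

    One symmetric superprogenitor division, then each progenitor divides
    asymmetrically into one CC and one PC.
    """
    progenitors = simulate_symmetric_divisions(1)
    cc = pc = 0
    for _ in range(progenitors):
        cc += 1
        pc += 1
    return cc, pc


def wildtype_census() -> dict[str, int]:
    """Expected per-hemisegment census from the error-free lineage model."""
    svp_cc, svp_pc = simulate_svp_lineage()
    return {
        "tin_cc": simulate_symmetric_divisions(2),
        "svp_cc": svp_cc,
        "svp_pc": svp_pc,
    }


@dataclass
class CellCountRecord:
    """One scored hemisegment.

    ``svp_pc`` and ``enlarged_svp_nucleus`` are ``None`` (missing) in the
    antibody assay, where Svp PCs are not visible.
    """

    embryo_id: str
    genotype: str
    segment: str
    side: str
    tin_cc: int
    svp_cc: int
    svp_pc: int | None
    enlarged_svp_nucleus: bool | None
    assay: str

    def validate(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"bad segment {self.segment!r}; expected A2..A8")
        if self.side not in SIDES:
            raise ValueError(f"bad side {self.side!r}; expected L or R")
        if self.assay not in ASSAYS:
            raise ValueError(f"bad assay {self.assay!r}")
        for name in ("tin_cc", "svp_cc"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.assay == SVP_LACZ:
            if self.svp_pc is None:
                raise ValueError(
                    f"svp_pc missing for {self.embryo_id}/{self.segment}{self.side} "
                    "in SVP_LACZ mode (Svp PCs are scorable and required)"
                )
            if not isinstance(self.svp_pc, (int, np.integer)) or self.svp_pc < 0:
                raise ValueError(f"svp_pc must be a non-negative integer, got {self.svp_pc!r}")
        else:
            if self.svp_pc is not None:
                raise ValueError(
                    "svp_pc must be missing in SVP_ANTIBODY mode "
                    "(Svp PCs are not visible in this assay)"
                )


@dataclass
class DefectCall:
    """Per-hemisegment defect flags.

    Fields that do not apply to the assay mode are ``None``: the antibody
    assay cannot separate the two Svp categories (``svp_earlier`` and
    ``svp_asymmetric`` are None, ``svp_combined`` is boolean) and vice versa
    in svp-lacZ mode.
    """

    tin_symmetric: bool
    svp_earlier: bool | None
    svp_asymmetric: bool | None
    svp_combined: bool | None
    unclassified_svp: bool
    assay: str

    def flags(self) -> dict[str, bool]:
        """Active category flags for this assay mode plus unclassified."""
        out = {TIN_SYMMETRIC: self.tin_symmetric}
        if self.assay == SVP_LACZ:
            out[SVP_EARLIER] = bool(self.svp_earlier)
            out[SVP_ASYMMETRIC] = bool(self.svp_asymmetric)
        else:
            out[SVP_COMBINED] = bool(self.svp_combined)
        out[UNCLASSIFIED_SVP] = self.unclassified_svp
        return out


def classify_hemisegment(record: CellCountRecord) -> DefectCall:
    """Apply the count-signature decision table to one hemisegment.

    svp-lacZ mode: (2,2) is normal; (1,1)/(3,3) → earlier symmetric defect;
    (1,3)/(3,1)/(2,1) → asymmetric defect; any other census is flagged
    ``unclassified_svp`` (reported separately, excluded from category
    numerators). Antibody mode: ``svp_combined`` := svp_cc != 2. In both
    modes ``tin_symmetric`` := tin_cc != 4, scored independently of the Svp
    flags. The karyokinesis signature (2,1) is recognised from counts alone;
    the enlarged-nucleus flag is advisory metadata.
    """
    record.validate()
    tin = record.tin_cc != EXPECTED_TIN_CC
    if record.assay == SVP_ANTIBODY:
        return DefectCall(
            tin_symmetric=tin,
            svp_earlier=None,
            svp_asymmetric=None,
            svp_combined=record.svp_cc != NORMAL_SVP_PATTERN[0],
            unclassified_svp=False,
            assay=record.assay,
        )
    pat = (record.svp_cc, record.svp_pc)
    earlier = pat in EARLIER_PATTERNS
    asym = pat in ASYMMETRIC_PATTERNS
    normal = pat == NORMAL_SVP_PATTERN
    return DefectCall(
        tin_symmetric=tin,
        svp_earlier=earlier,
        svp_asymmetric=asym,
        svp_combined=None,
        unclassified_svp=not (earlier or asym or normal),
        assay=record.assay,
    )


def classify_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized decision table: add one boolean column per category.

    Accepts a count table in the CSV schema (possibly mixed assays) and
    returns a copy with ``tin_symmetric``, ``svp_earlier``,
    ``svp_asymmetric``, ``svp_combined`` and ``unclassified_svp`` columns.
    Columns that do not apply to a row's assay are False.
    """
    df = frame.copy()
    tin = df["tin_cc"].to_numpy(dtype=np.int64)
    cc = df["svp_cc"].to_numpy(dtype=np.int64)
    pc = pd.array(df["svp_pc"], dtype="Int64").to_numpy(dtype=np.int64, na_value=-1)
    lacz = (df["assay"] == SVP_LACZ).to_numpy()
    if np.any((pc < 0) & lacz):
        bad = df.loc[lacz & (pc < 0), "embryo_id"].iloc[0]
        raise ValueError(f"svp_pc missing in SVP_LACZ mode (embryo {bad})")

    df[TIN_SYMMETRIC] = tin != EXPECTED_TIN_CC
    earlier = np.zeros(len(df), bool)
    asym = np.zeros(len(df), bool)
    for a, b in EARLIER_PATTERNS:
        earlier |= (cc == a) & (pc == b)
    for a, b in ASYMMETRIC_PATTERNS:
        asym |= (cc == a) & (pc == b)
    normal = (cc == NORMAL_SVP_PATTERN[0]) & (pc == NORMAL_SVP_PATTERN[1])
    df[SVP_EARLIER] = earlier & lacz
    df[SVP_ASYMMETRIC] = asym & lacz
    df[SVP_COMBINED] = (cc != NORMAL_SVP_PATTERN[0]) & ~lacz
    df[UNCLASSIFIED_SVP] = ~(earlier | asym | normal) & lacz
    return df


@dataclass
class EmbryoSummary:
    """Per-embryo defect counts and exact proportions (the Y_j of the models)."""

    embryo_id: str
    genotype: str
    assay: str
    n_hemisegments: int
    defects_per_category: dict[str, int]
    proportion_per_category: dict[str, Fraction]


def summarize_embryo(records: Sequence[CellCountRecord]) -> EmbryoSummary:
    """Classify one embryo's hemisegments and count defects per category.

    Proportions are exact rationals (defects / n_hemisegments); a hemisegment
    carrying both a Tin and an Svp defect counts once in each category.
    """
    if not records:
        raise ValueError("no records for embryo")
    ids = {r.embryo_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records span multiple embryos: {sorted(ids)}")
    if len({r.genotype for r in records}) != 1 or len({r.assay for r in records}) != 1:
        raise ValueError("records for one embryo must share genotype and assay")
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.segment, r.side)
        if key in seen:
            raise ValueError(
                f"duplicate hemisegment {r.segment}{r.side} for embryo {r.embryo_id}"
            )
        seen.add(key)
    assay = records[0].assay
    cats = categories_for_assay(assay) + (UNCLASSIFIED_SVP,)
    counts = {c: 0 for c in cats}
    for r in records:
        for cat, flag in classify_hemisegment(r).flags().items():
            if flag:
                counts[cat] += 1
    n = len(records)
    return EmbryoSummary(
        embryo_id=records[0].embryo_id,
        genotype=records[0].genotype,
        assay=assay,
        n_hemisegments=n,
        defects_per_category=counts,
        proportion_per_category={c: Fraction(k, n) for c, k in counts.items()},
    )


def summarize_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-embryo summary table (vectorized path used by pipeline/simulations).

    Returns one row per embryo with ``n_hemisegments``, per-category defect
    counts ``n_<category>`` and float proportions ``prop_<category>``.
    """
    if frame.empty:
        raise ValueError("no records")
    assays = frame["assay"].unique()
    if len(assays) != 1:
        raise ValueError(f"mixed assays in one table: {sorted(assays)}")
    cats = categories_for_assay(assays[0]) + (UNCLASSIFIED_SVP,)
    df = classify_table(frame)
    dup = df.duplicated(subset=["embryo_id", "segment", "side"])
    if dup.any():
        r = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate hemisegment {r['segment']}{r['side']} for embryo {r['embryo_id']}"
        )
    g = df.groupby(["embryo_id", "genotype", "assay"], sort=True)
    out = g.size().rename("n_hemisegments").to_frame()
    for c in cats:
        out[f"n_{c}"] = g[c].sum()
        out[f"prop_{c}"] = out[f"n_{c}"] / out["n_hemisegments"]
    return out.reset_index()


def _summaries_to_frame(summaries: Sequence[EmbryoSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "embryo_id": s.embryo_id,
            "genotype": s.genotype,
            "assay": s.assay,
            "n_hemisegments": s.n_hemisegments,
        }
        for c, k in s.defects_per_category.items():
            row[f"n_{c}"] = k
            row[f"prop_{c}"] = k / s.n_hemisegments
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_genotype(
    summaries: Sequence[EmbryoSummary] | pd.DataFrame,
) -> pd.DataFrame:
    """Pool embryo summaries into a per-(genotype, category) table.

    Returns columns: genotype, category, n_embryos, n_hemisegments,
    n_defective, pooled_pct (100 × Σdefects / Σhemisegments) and
    mean_proportion (unweighted mean of per-embryo proportions — the
    quantity the permutation tests model).
    """
    df = summaries if isinstance(summaries, pd.DataFrame) else _summaries_to_frame(summaries)
    if df.empty:
        raise ValueError("no summaries")
    assays = df["assay"].unique()
    if len(assays) != 1:
        raise ValueError(f"mixed assays: {sorted(assays)}")
    cats = categories_for_assay(assays[0]) + (UNCLASSIFIED_SVP,)
    rows = []
    for genotype, sub in df.groupby("genotype", sort=True):
        hemi = int(sub["n_hemisegments"].sum())
        for c in cats:
            defective = int(sub[f"n_{c}"].sum())
            rows.append({
                "genotype": genotype,
                "category": c,
                "n_embryos": len(sub),
                "n_hemisegments": hemi,
                "n_defective": defective,
                "pooled_pct": 100.0 * defective / hemi,
                "mean_proportion": float(sub[f"prop_{c}"].mean()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 3. Synthetic cohorts
# ---------------------------------------------------------------------------

MAX_RATE = 0.95  # keep the logit finite after additive shifts
_ZERO_RATE_SUB = 1e-6

ROLE_CONTROL = "control"
ROLE_SINGLE_1 = "single_het_1"
ROLE_SINGLE_2 = "single_het_2"
ROLE_DOUBLE = "double_het"
ROLE_WILDTYPE = "wildtype"
ROLE_MUTANT = "mutant"


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Per-hemisegment defect probabilities are additive on the probability
    scale — ``baseline_rate[c] + main_effect[g][c]`` plus
    ``interaction_effect[c]`` for the genotype whose role is ``double_het`` —
    clipped to [0, 0.95]. Within-embryo correlation enters on the logit
    scale: each embryo draws one Normal(0, embryo_sd²) effect per category,
    added to the logit of its genotype rate, which makes hemisegments of an
    embryo share a defect propensity (overdispersion relative to binomial)
    while keeping the additive-sum synergy definition exactly representable
    in the configured rates.

    With ``rates_are_marginal=True`` the configured rates are targets for
    the *marginal* (population-average) defect frequency: the latent logit
    intercept is solved so that E_u[expit(logit(p) + u)] equals the
    configured rate. Synergy is defined on marginal percentages (the
    additive-sum dashed line is a sum of observed frequencies), so this mode
    makes "double = sum of singles" hold exactly at any embryo_sd, not only
    at zero dispersion; it is the mode the simulation scenarios use.
    """

    n_embryos: dict[str, int]
    segments: tuple[tuple[str, str], ...] = field(default_factory=default_segments)
    baseline_rate: dict[str, float] = field(
        default_factory=lambda: {TIN_SYMMETRIC: 0.025, SVP_EARLIER: 0.01, SVP_ASYMMETRIC: 0.005}
    )
    embryo_sd: float = 0.5
    main_effect: dict[str, dict[str, float]] = field(default_factory=dict)
    interaction_effect: dict[str, float] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    assay: str = SVP_LACZ
    tin_defect_counts: tuple[int, ...] = (3, 5)
    rates_are_marginal: bool = False

    def __post_init__(self) -> None:
        if self.embryo_sd < 0:
            raise ValueError("embryo_sd must be >= 0")
        if self.assay not in ASSAYS:
            raise ValueError(f"bad assay {self.assay!r}")
        for g, n in self.n_embryos.items():
            if n < 1:
                raise ValueError(f"genotype {g!r} has {n} embryos; need >= 1")

    def rate(self, genotype: str, category: str) -> float:
        """Configured per-hemisegment defect probability, clipped to [0, 0.95]."""
        p = self.baseline_rate.get(category, 0.0)
        p += self.main_effect.get(genotype, {}).get(category, 0.0)
        if self.roles.get(genotype) == ROLE_DOUBLE:
            p += self.interaction_effect.get(category, 0.0)
        return float(min(max(p, 0.0), MAX_RATE))

    def truth(self) -> dict:
        """True rates per genotype/category plus the interaction truth.

        When single/double heterozygote roles are assigned, the per-category
        interaction truth is rate(double) − rate(single1) − rate(single2),
        the expected value of the intercept-free model's b3.
        """
        rates = {
            g: {c: self.rate(g, c) for c in CATEGORIES_LACZ}
            for g in self.n_embryos
        }
        out: dict = {
            "rates": rates,
            "baseline_rate": dict(self.baseline_rate),
            "interaction_effect": dict(self.interaction_effect),
            "embryo_sd": self.embryo_sd,
            "seed": self.seed,
        }
        by_role = {r: g for g, r in self.roles.items()}
        if {ROLE_SINGLE_1, ROLE_SINGLE_2, ROLE_DOUBLE} <= set(by_role):
            out["interaction_truth"] = {
                c: rates[by_role[ROLE_DOUBLE]][c]
                - rates[by_role[ROLE_SINGLE_1]][c]
                - rates[by_role[ROLE_SINGLE_2]][c]
                for c in CATEGORIES_LACZ
            }
        return out


@dataclass
class SyntheticCohort:
    records: list[CellCountRecord]
    truth: dict

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


_warned_zero_rate: set[tuple[str, str]] = set()

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)
_latent_rate_cache: dict[tuple[float, float], float] = {}


def _marginal_rate(latent_logit: float, sd: float) -> float:
    """E_u[expit(latent_logit + u)] for u ~ Normal(0, sd²) (Gauss–Hermite)."""
    vals = expit(latent_logit + math.sqrt(2.0) * sd * _GH_NODES)
    return float((_GH_WEIGHTS * vals).sum() / math.sqrt(math.pi))


def latent_rate_for_marginal(target: float, sd: float) -> float:
    """Latent rate whose logit-normal mixture has marginal mean ``target``.

    Monotone bisection on the latent logit; the marginal mean of the mixture
    exceeds the latent rate for rates below 1/2 (Jensen), so the latent rate
    returned is slightly below ``target``.
    """
    if not 0 < target < 1:
        raise ValueError("target marginal rate must be in (0, 1)")
    if sd == 0:
        return target
    key = (round(target, 12), round(sd, 12))
    if key in _latent_rate_cache:
        return _latent_rate_cache[key]
    lo, hi = -40.0, 40.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _marginal_rate(mid, sd) < target:
            lo = mid
        else:
            hi = mid
    p = float(expit(0.5 * (lo + hi)))
    _latent_rate_cache[key] = p
    return p


def draw_defect_flags(
    config: GeneratorConfig, genotype: str, rng: np.random.Generator, n: int
) -> dict[str, np.ndarray]:
    """Latent per-hemisegment defect indicators for one embryo.

    One embryo-level logit shift u ~ N(0, embryo_sd²) is drawn per category;
    each of the ``n`` hemisegments is then defective with probability
    inverse-logit(logit(p) + u). A configured rate of exactly 0 with
    embryo_sd > 0 is substituted by 1e-6 (the logit of 0 is undefined) with a
    warning; with embryo_sd = 0 the rate is used directly, so the degenerate
    zero-rate cohort is exactly defect-free.
    """
    flags = {}
    for cat in CATEGORIES_LACZ:
        p = config.rate(genotype, cat)
        if config.embryo_sd > 0:
            if p <= 0.0:
                key = (genotype, cat)
                if key not in _warned_zero_rate:
                    _warned_zero_rate.add(key)
                    logger.warning(
                        "rate 0 for genotype %s category %s with embryo_sd > 0; "
                        "substituting %g", genotype, cat, _ZERO_RATE_SUB,
                    )
                p = _ZERO_RATE_SUB
            if config.rates_are_marginal:
                p = latent_rate_for_marginal(p, config.embryo_sd)
            u = rng.normal(0.0, config.embryo_sd)
            q = float(expit(logit(p) + u))
        else:
            q = p
        flags[cat] = rng.random(n) < q
    return flags


def sample_embryo(
    config: GeneratorConfig,
    genotype: str,
    rng: np.random.Generator,
    embryo_id: str = "e001",
) -> list[CellCountRecord]:
    """Materialize one embryo as count records.

    Defects become census signatures: Tin → tin_cc drawn uniformly from
    ``tin_defect_counts``; svp_earlier → (1,1) or (3,3); svp_asymmetric →
    (1,3), (3,1) or the karyokinesis (2,1) (which also sets the
    enlarged-nucleus flag). If both Svp categories fire on one hemisegment,
    svp_earlier takes precedence (deterministic, logged at debug level).
    """
    n = len(config.segments)
    flags = draw_defect_flags(config, genotype, rng, n)
    earlier = flags[SVP_EARLIER]
    asym = flags[SVP_ASYMMETRIC] & ~earlier
    n_collide = int((flags[SVP_ASYMMETRIC] & earlier).sum())
    if n_collide:
        logger.debug(
            "%d hemisegment(s) drew both Svp categories; svp_earlier kept", n_collide
        )
    antibody = config.assay == SVP_ANTIBODY
    records = []
    for i, (seg, side) in enumerate(config.segments):
        if flags[TIN_SYMMETRIC][i]:
            tin_cc = int(config.tin_defect_counts[rng.integers(len(config.tin_defect_counts))])
        else:
            tin_cc = EXPECTED_TIN_CC
        if earlier[i]:
            svp = EARLIER_PATTERNS[rng.integers(len(EARLIER_PATTERNS))]
        elif asym[i]:
            svp = ASYMMETRIC_PATTERNS[rng.integers(len(ASYMMETRIC_PATTERNS))]
        else:
            svp = NORMAL_SVP_PATTERN
        records.append(CellCountRecord(
            embryo_id=embryo_id,
            genotype=genotype,
            segment=seg,
            side=side,
            tin_cc=tin_cc,
            svp_cc=svp[0],
            svp_pc=None if antibody else svp[1],
            enlarged_svp_nucleus=None if antibody else (svp == KARYOKINESIS_PATTERN),
            assay=config.assay,
        ))
    return records


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate all embryos of a cohort from one seeded RNG stream.

    The seed fully determines the output; embryo order is generation order
    (genotypes in config order, embryos numbered within genotype).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[CellCountRecord] = []
    for genotype, n_emb in config.n_embryos.items():
        for i in range(n_emb):
            records.extend(
                sample_embryo(config, genotype, rng, embryo_id=f"{genotype}-e{i + 1:03d}")
            )
    return SyntheticCohort(records=records, truth=config.truth())


def generator_config_from_yaml(path: str | Path) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML file mirroring its fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "segments" in data:
        data["segments"] = tuple((s, d) for s, d in data["segments"])
    if "tin_defect_counts" in data:
        data["tin_defect_counts"] = tuple(data["tin_defect_counts"])
    return GeneratorConfig(**data)


# ---------------------------------------------------------------------------
# 4. Permutation inference
# ---------------------------------------------------------------------------

@dataclass
class ProportionSample:
    """Per-embryo proportions with a binary design.

    ``indicators`` is (n,) for the two-group model or (n, 2) = [Ip, Iq] for
    the interaction model; the embryo is the exchangeable unit throughout.
    """

    y: np.ndarray
    group_labels: np.ndarray
    indicators: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        self.indicators = np.asarray(self.indicators, dtype=float)
        if np.any((self.y < 0) | (self.y > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        if self.indicators.shape[0] != self.y.shape[0]:
            raise ValueError("indicators and y length mismatch")
        if not np.isin(self.indicators, (0.0, 1.0)).all():
            raise ValueError("indicators must be binary")

    @classmethod
    def two_group(
        cls, summary: pd.DataFrame, category: str, group1: str, group0: str
    ) -> "ProportionSample":
        """Build a two-group sample from a ``summarize_table`` frame."""
        sub = summary[summary["genotype"].isin([group0, group1])]
        if sub.empty:
            raise ValueError(f"no embryos for groups {group0!r}/{group1!r}")
        y = sub[f"prop_{category}"].to_numpy(float)
        labels = sub["genotype"].to_numpy()
        return cls(y=y, group_labels=labels, indicators=(labels == group1).astype(float))

    @classmethod
    def interaction(
        cls, summary: pd.DataFrame, category: str, roles: Mapping[str, str],
        include_control: bool = False,
    ) -> "ProportionSample":
        """Build an interaction sample: (Ip, Iq) per embryo from genotype roles."""
        coding = {ROLE_SINGLE_1: (1.0, 0.0), ROLE_SINGLE_2: (0.0, 1.0),
                  ROLE_DOUBLE: (1.0, 1.0)}
        if include_control:
            coding[ROLE_CONTROL] = (0.0, 0.0)
        rows, design = [], []
        for _, r in summary.iterrows():
            role = roles.get(r["genotype"])
            if role in coding:
                rows.append(r)
                design.append(coding[role])
        if not rows:
            raise ValueError("no embryos match the interaction roles")
        sub = pd.DataFrame(rows)
        return cls(
            y=sub[f"prop_{category}"].to_numpy(float),
            group_labels=sub["genotype"].to_numpy(),
            indicators=np.asarray(design),
        )


@dataclass
class PermutationConfig:
    """Settings for the permutation tests.

    ``n_permutations`` defaults to 10^6, the value used for highly
    reproducible p-values; the CLI lowers it to 10^4 by default. The strict
    tie rule counts permuted statistics strictly exceeding the observed one;
    ``geq`` is the conservative variant for tied proportion data. Samples
    with at most ``exhaustive_threshold`` distinct arrangements are
    enumerated exactly instead of sampled.
    """

    n_permutations: int = 1_000_000
    tail: str = "upper"           # or "two_sided"
    tie_rule: str = "strict"      # or "geq"
    exhaustive_threshold: int = 100_000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tail not in ("upper", "two_sided"):
            raise ValueError(f"bad tail {self.tail!r}")
        if self.tie_rule not in ("strict", "geq"):
            raise ValueError(f"bad tie_rule {self.tie_rule!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PermutationResult:
    """Outcome of one permutation test.

    ``p_value == (exceedances + 1) / (n_permutations + 1)`` in both modes; in
    exhaustive mode ``n_permutations`` counts the distinct non-identity
    arrangements, so the identity arrangement is the +1 of the exact-test
    convention.
    """

    coefficient: float
    exceedances: int
    n_permutations: int
    p_value: float
    exhaustive: bool
    scheme: str                   # "label_permutation" or "smith"
    seed: int | None
    tie_rule: str = "strict"
    tail: str = "upper"
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficient"] = float(d["coefficient"])
        d["p_value"] = float(d["p_value"])
        return d


_TIE_TOL = 1e-9  # proportion-scale tolerance separating ties from exceedances


def _exceeds(stats: np.ndarray, observed: float, tie_rule: str, tail: str) -> np.ndarray:
    if tail == "two_sided":
        stats, observed = np.abs(stats), abs(observed)
    if tie_rule == "strict":
        return stats > observed + _TIE_TOL
    return stats > observed - _TIE_TOL


def ols_fit(
    design: np.ndarray, y: np.ndarray, column_names: Sequence[str] | None = None
) -> np.ndarray:
    """Least-squares coefficients, refusing rank-deficient designs.

    On rank deficiency the error names the columns lying in the span of the
    others (e.g. the empty-group indicator).
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and response length mismatch")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        names = list(column_names) if column_names else [f"x{i}" for i in range(X.shape[1])]
        bad = [
            names[j] for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == r
        ]
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def pvalue_from_exceedances(n: int, n_permutations: int, tie_rule: str = "strict") -> float:
    """p = (n+1)/(N+1): the Monte-Carlo permutation p-value estimator."""
    if tie_rule not in ("strict", "geq"):
        raise ValueError(f"bad tie_rule {tie_rule!r}")
    if not 0 <= n <= n_permutations:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={n_permutations}")
    return (n + 1) / (n_permutations + 1)


def _two_group_stat(y: np.ndarray, n1: int, s1: np.ndarray | float) -> np.ndarray | float:
    """b1 = mean(y | I=1) − mean(y | I=0) from the group-1 sum."""
    n0 = len(y) - n1
    total = y.sum()
    return s1 / n1 - (total - s1) / n0


def two_group_perm_test(
    sample: ProportionSample, config: PermutationConfig
) -> PermutationResult:
    """Permutation test of b1 in Y_j = b0 + b1·I_j + e_j.

    The embryo is the permutation unit: genotype labels are shuffled among
    embryos (never among hemisegments). If the number of distinct label
    arrangements C(n, n1) is at most ``exhaustive_threshold`` every
    arrangement is enumerated; otherwise N Monte-Carlo shuffles are drawn and
    p = (n+1)/(N+1).
    """
    I = sample.indicators
    if I.ndim != 1:
        raise ValueError("two-group test needs a single indicator column")
    y = sample.y
    n = len(y)
    n1 = int(I.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be non-empty")
    degenerate = min(n0, n1) < 2
    if degenerate:
        warnings.warn(
            "a group has fewer than 2 embryos; the permutation test is degenerate",
            UserWarning,
        )
    observed = float(_two_group_stat(y, n1, y[I == 1].sum()))
    total_arrangements = math.comb(n, n1)

    if total_arrangements <= config.exhaustive_threshold:
        identity = frozenset(np.flatnonzero(I == 1).tolist())
        count = 0
        for pos in itertools.combinations(range(n), n1):
            if frozenset(pos) == identity:
                continue
            stat = _two_group_stat(y, n1, y[list(pos)].sum())
            if _exceeds(np.asarray([stat]), observed, config.tie_rule, config.tail)[0]:
                count += 1
        N = total_arrangements - 1
        return PermutationResult(
            coefficient=observed, exceedances=count, n_permutations=N,
            p_value=pvalue_from_exceedances(count, N, config.tie_rule),
            exhaustive=True, scheme="label_permutation", seed=None,
            tie_rule=config.tie_rule, tail=config.tail, degenerate=degenerate,
        )

    rng = np.random.default_rng(config.seed)
    N = config.n_permutations
    count = 0
    chunk = max(1, 2_000_000 // n)
    done = 0
    while done < N:
        m = min(chunk, N - done)
        idx = np.argsort(rng.random((m, n)), axis=1)[:, :n1]
        s1 = y[idx].sum(axis=1)
        stats = _two_group_stat(y, n1, s1)
        count += int(_exceeds(stats, observed, config.tie_rule, config.tail).sum())
        done += m
    return PermutationResult(
        coefficient=observed, exceedances=count, n_permutations=N,
        p_value=pvalue_from_exceedances(count, N, config.tie_rule),
        exhaustive=False, scheme="label_permutation", seed=config.seed,
        tie_rule=config.tie_rule, tail=config.tail, degenerate=degenerate,
    )


def smith_orthogonalize(nuisance: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Residualize the regressor of interest against the nuisance columns.

    Returns g⊥ = g − Z (ZᵀZ)⁻¹ Zᵀ g, orthogonal to every nuisance column to
    1e-10 relative tolerance (a second projection pass is applied if the
    first leaves residual correlation).
    """
    Z = np.asarray(nuisance, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    g = np.asarray(target, dtype=float)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError("nuisance columns are rank deficient")
    coef, *_ = np.linalg.lstsq(Z, g, rcond=None)
    g_perp = g - Z @ coef
    scale = max(np.linalg.norm(g), 1e-300) * np.linalg.norm(Z, axis=0).max()
    if np.abs(Z.T @ g_perp).max() > 1e-10 * scale:
        coef2, *_ = np.linalg.lstsq(Z, g_perp, rcond=None)
        g_perp = g_perp - Z @ coef2
    assert np.abs(Z.T @ g_perp).max() <= 1e-10 * scale
    return g_perp


def _multiset_arrangement_count(counts: np.ndarray) -> int:
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _iter_multiset_arrangements(
    values: np.ndarray, counts: np.ndarray, n: int
) -> Iterable[np.ndarray]:
    """Yield every distinct arrangement of the multiset as a float vector."""
    out = np.empty(n, dtype=float)

    def rec(free: tuple[int, ...], k: int):
        if k == len(values) - 1:
            out[list(free)] = values[k]
            yield out
            return
        for subset in itertools.combinations(free, int(counts[k])):
            out[list(subset)] = values[k]
            rest = tuple(i for i in free if i not in set(subset))
            yield from rec(rest, k + 1)

    yield from rec(tuple(range(n)), 0)


def interaction_perm_test(
    sample: ProportionSample,
    config: PermutationConfig,
    with_intercept: bool = False,
) -> PermutationResult:
    """Smith-scheme permutation test of the synergy coefficient b3.

    Fits Y_j = b1·Ip_j + b2·Iq_j + b3·Ip_j·Iq_j + e_j without intercept on
    the two single-heterozygote groups and the double heterozygote, so
    b3 = mean(double) − mean(singleP) − mean(singleQ) — the departure from
    the additive expectation. The interaction column is orthogonalized
    against the main-effect columns; each permutation shuffles the
    orthogonalized regressor's entries across embryos and records its
    coefficient against the nuisance-residualized response with the fixed
    denominator ‖g⊥‖²:

        stat(π) = π(g⊥)·M_Z y / ‖g⊥‖²,   M_Z = I − Z(ZᵀZ)⁻¹Zᵀ.

    Because g⊥ ⊥ Z, the identity arrangement gives exactly the fitted b3,
    so observed and permuted statistics share one formula and are
    exchangeable under the null; refitting the full model per permutation
    instead (a random denominator on a non-pivotal coefficient) widens the
    permutation distribution and makes the test measurably conservative.
    ``with_intercept=True`` adds b0 and admits control ((0,0)) embryos.
    """
    if sample.indicators.ndim != 2 or sample.indicators.shape[1] != 2:
        raise ValueError("interaction test needs (Ip, Iq) indicator columns")
    Ip, Iq = sample.indicators[:, 0], sample.indicators[:, 1]
    y = sample.y
    groups = {(1, 0): "single_het_1", (0, 1): "single_het_2", (1, 1): "double_het"}
    for pat, name in groups.items():
        if not np.any((Ip == pat[0]) & (Iq == pat[1])):
            raise ValueError(f"{name} group ((Ip,Iq)=={pat}) is empty")
    has_controls = bool(np.any((Ip == 0) & (Iq == 0)))
    if has_controls and not with_intercept:
        raise ValueError(
            "control ((0,0)) embryos require with_intercept=True; the literal "
            "intercept-free model is fit on the three mutant groups only"
        )

    g = Ip * Iq
    if with_intercept:
        Z = np.column_stack([np.ones_like(Ip), Ip, Iq])
        names = ["intercept", "Ip", "Iq", "Ip*Iq"]
    else:
        Z = np.column_stack([Ip, Iq])
        names = ["Ip", "Iq", "Ip*Iq"]
    g_perp = smith_orthogonalize(Z, g)
    if np.linalg.norm(g_perp) <= 1e-12 * max(1.0, np.linalg.norm(g)):
        raise ValueError("interaction not identifiable: orthogonalized regressor is zero")

    beta = ols_fit(np.column_stack([Z, g]), y, column_names=names)
    observed = float(beta[-1])

    # stat(pi) = pi(g_perp)' M_Z y / ||g_perp||^2; the identity arrangement
    # reproduces the fitted b3 exactly (g_perp' M_Z y = g_perp' y).
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    hat = Z @ ZtZ_inv @ Z.T
    r_y = y - hat @ y
    gg = float(g_perp @ g_perp)

    n = len(y)
    values, counts = np.unique(np.round(g_perp, 12), return_counts=True)
    total_arrangements = _multiset_arrangement_count(counts)

    if total_arrangements <= config.exhaustive_threshold:
        identity = np.round(g_perp, 12)
        count = 0
        seen_identity = False
        for arr in _iter_multiset_arrangements(values, counts, n):
            if not seen_identity and np.array_equal(arr, identity):
                seen_identity = True
                continue
            stat = float(arr @ r_y) / gg
            if _exceeds(np.asarray([stat]), observed, config.tie_rule, config.tail)[0]:
                count += 1
        N = total_arrangements - 1
        return PermutationResult(
            coefficient=observed, exceedances=count, n_permutations=N,
            p_value=pvalue_from_exceedances(count, N, config.tie_rule),
            exhaustive=True, scheme="smith", seed=None,
            tie_rule=config.tie_rule, tail=config.tail,
        )

    rng = np.random.default_rng(config.seed)
    N = config.n_permutations
    count = 0
    chunk = max(1, 2_000_000 // n)
    done = 0
    while done < N:
        m = min(chunk, N - done)
        idx = np.argsort(rng.random((m, n)), axis=1)
        stats = (g_perp[idx] @ r_y) / gg
        count += int(_exceeds(stats, observed, config.tie_rule, config.tail).sum())
        done += m
    return PermutationResult(
        coefficient=observed, exceedances=count, n_permutations=N,
        p_value=pvalue_from_exceedances(count, N, config.tie_rule),
        exhaustive=False, scheme="smith", seed=config.seed,
        tie_rule=config.tie_rule, tail=config.tail,
    )


def synergy_call(result: PermutationResult, alpha: float = 0.05) -> str:
    """"synergistic" iff b3 > 0 and p <= alpha, else "not_synergistic".

    A negative b3 (defects at or below the additive sum) is never called
    synergistic regardless of p.
    """
    if result.coefficient > 0 and result.p_value <= alpha:
        return "synergistic"
    return "not_synergistic"


# --- simulation-study harness ----------------------------------------------

def two_group_null_scenario(
    rate: float = 0.10,
    n_embryos: int = 15,
    embryo_sd: float = 0.5,
    category: str = TIN_SYMMETRIC,
) -> GeneratorConfig:
    """Two genotypes with identical defect rates: the exchangeable null.

    The default rate of 0.10 sits in the middle of the defect-frequency range
    where mutant-vs-control comparisons actually operate.
    """
    baseline = {TIN_SYMMETRIC: 0.025, SVP_EARLIER: 0.01, SVP_ASYMMETRIC: 0.005}
    baseline[category] = rate
    return GeneratorConfig(
        n_embryos={"wildtype": n_embryos, "mutant": n_embryos},
        baseline_rate=baseline,
        embryo_sd=embryo_sd,
        roles={"wildtype": ROLE_WILDTYPE, "mutant": ROLE_MUTANT},
        rates_are_marginal=True,
    )


def interaction_scenarios(
    deltas: Sequence[float] = (0.0, 0.05, 0.10, 0.15),
    n_embryos: int = 15,
    embryo_sd: float = 0.5,
    main_p: float = 0.05,
    main_q: float = 0.05,
    category: str = TIN_SYMMETRIC,
) -> dict[str, GeneratorConfig]:
    """Graded-synergy scenarios for the interaction test.

    The tested category's baseline is zero, so the single heterozygotes sit
    at their main effects and the double heterozygote at main_p + main_q + δ:
    δ = 0 is then exactly the additive null (b3 = 0) and the interaction
    truth equals δ. Other categories keep small non-zero background rates.
    """
    out = {}
    for d in deltas:
        baseline = {TIN_SYMMETRIC: 0.01, SVP_EARLIER: 0.01, SVP_ASYMMETRIC: 0.005}
        baseline[category] = 0.0
        out[f"delta={d:.2f}"] = GeneratorConfig(
            n_embryos={"P_het": n_embryos, "Q_het": n_embryos, "PQ_het": n_embryos},
            baseline_rate=baseline,
            embryo_sd=embryo_sd,
            main_effect={
                "P_het": {category: main_p},
                "Q_het": {category: main_q},
                "PQ_het": {category: main_p + main_q},
            },
            interaction_effect={category: d},
            roles={"P_het": ROLE_SINGLE_1, "Q_het": ROLE_SINGLE_2, "PQ_het": ROLE_DOUBLE},
            rates_are_marginal=True,
        )
    return out


def simulation_study(
    scenarios: Mapping[str, GeneratorConfig],
    perm_config: PermutationConfig,
    n_reps: int,
    test: str = "interaction",
    category: str = TIN_SYMMETRIC,
    seed: int = 0,
) -> pd.DataFrame:
    """Rejection rates of a permutation test over replicated synthetic cohorts.

    For each scenario, ``n_reps`` cohorts are generated (fresh generator and
    permutation seeds drawn from one master stream), run through the full
    classify → summarize → test pipeline, and the fraction of p-values at or
    below ``perm_config.alpha`` is reported with its binomial standard error
    and the mean fitted coefficient.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    master = np.random.default_rng(seed)
    rows = []
    for name, gcfg in scenarios.items():
        rejections = 0
        coefs = np.empty(n_reps)
        for rep in range(n_reps):
            gseed = int(master.integers(2**31))
            pseed = int(master.integers(2**31))
            cohort = generate_cohort(gcfg, seed=gseed)
            summary = summarize_table(cohort.frame)
            if test == "interaction":
                s = ProportionSample.interaction(summary, category, gcfg.roles)
                res = interaction_perm_test(s, replace(perm_config, seed=pseed))
            elif test == "two_group":
                by_role = {r: g for g, r in gcfg.roles.items()}
                g1 = by_role.get(ROLE_MUTANT, list(gcfg.n_embryos)[-1])
                g0 = by_role.get(ROLE_WILDTYPE, list(gcfg.n_embryos)[0])
                s = ProportionSample.two_group(summary, category, group1=g1, group0=g0)
                res = two_group_perm_test(s, replace(perm_config, seed=pseed))
            else:
                raise ValueError(f"unknown test {test!r}")
            coefs[rep] = res.coefficient
            if res.p_value <= perm_config.alpha:
                rejections += 1
        rate = rejections / n_reps
        rows.append({
            "scenario": name,
            "test": test,
            "category": category,
            "n_reps": n_reps,
            "rejections": rejections,
            "rejection_rate": rate,
            "se": math.sqrt(rate * (1 - rate) / n_reps),
            "mean_coefficient": float(coefs.mean()),
            "sd_coefficient": float(coefs.std(ddof=1)) if n_reps > 1 else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 5. Pipeline: IO, reports, orchestration
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[CellCountRecord]) -> pd.DataFrame:
    """Count records as a DataFrame in the CSV column schema."""
    df = pd.DataFrame([asdict(r) for r in records], columns=list(COUNT_COLUMNS))
    df["svp_pc"] = pd.array(df["svp_pc"], dtype="Int64")
    return df


def frame_to_records(frame: pd.DataFrame) -> list[CellCountRecord]:
    records = []
    for row in frame.itertuples(index=False):
        svp_pc = row.svp_pc
        svp_pc = None if pd.isna(svp_pc) else int(svp_pc)
        enl = row.enlarged_svp_nucleus
        enl = None if (enl is None or (isinstance(enl, float) and math.isnan(enl))) else bool(enl)
        records.append(CellCountRecord(
            embryo_id=str(row.embryo_id), genotype=str(row.genotype),
            segment=str(row.segment), side=str(row.side),
            tin_cc=int(row.tin_cc), svp_cc=int(row.svp_cc),
            svp_pc=svp_pc, enlarged_svp_nucleus=enl, assay=str(row.assay),
        ))
    return records


def write_counts(
    records: Sequence[CellCountRecord] | pd.DataFrame, path: str | Path
) -> None:
    """Write a count table (CSV or TSV by extension); missing values as empty cells."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    out = df.copy()
    out["enlarged_svp_nucleus"] = out["enlarged_svp_nucleus"].map(
        lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else str(bool(v))
    )
    out.to_csv(path, sep=sep, index=False, na_rep="")


_TRUE_STRINGS = {"true", "1", "yes"}
_FALSE_STRINGS = {"false", "0", "no"}


def _parse_int(value: str, column: str, line: int) -> int:
    try:
        v = int(value)
    except ValueError:
        raise ValueError(f"line {line}: non-integer {column} {value!r}") from None
    if v < 0:
        raise ValueError(f"line {line}: negative {column} {value!r}")
    return v


def read_counts(path: str | Path, assay: str | None = None) -> list[CellCountRecord]:
    """Read and validate a hemisegment count table.

    The header must contain exactly the schema columns; empty cells are
    missing values. Errors name the offending 1-based file line. ``assay``
    optionally asserts a uniform assay mode.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if set(df.columns) != set(COUNT_COLUMNS):
        unknown = sorted(set(df.columns) - set(COUNT_COLUMNS))
        missing = sorted(set(COUNT_COLUMNS) - set(df.columns))
        raise ValueError(
            f"{path}: bad header; unknown columns {unknown}, missing columns {missing}"
        )
    if df.empty:
        raise ValueError(f"{path}: no records")
    records = []
    seen: dict[tuple[str, str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        row_assay = getattr(row, "assay").strip()
        if row_assay not in ASSAYS:
            raise ValueError(f"line {line}: bad assay {row_assay!r}")
        if assay is not None and row_assay != assay:
            raise ValueError(f"line {line}: assay {row_assay!r} != expected {assay!r}")
        segment = getattr(row, "segment").strip()
        if segment not in SEGMENTS:
            raise ValueError(f"line {line}: bad segment name {segment!r}")
        side = getattr(row, "side").strip()
        if side not in SIDES:
            raise ValueError(f"line {line}: bad side {side!r}")
        key = (getattr(row, "embryo_id"), segment, side)
        if key in seen:
            raise ValueError(
                f"line {line}: duplicate hemisegment {key[1]}{key[2]} for embryo "
                f"{key[0]!r} (first at line {seen[key]})"
            )
        seen[key] = line
        svp_pc_raw = getattr(row, "svp_pc").strip()
        if row_assay == SVP_LACZ:
            if svp_pc_raw == "":
                raise ValueError(f"line {line}: svp_pc missing in SVP_LACZ mode")
            svp_pc = _parse_int(svp_pc_raw, "svp_pc", line)
        else:
            if svp_pc_raw != "":
                raise ValueError(
                    f"line {line}: svp_pc must be empty in SVP_ANTIBODY mode"
                )
            svp_pc = None
        enl_raw = getattr(row, "enlarged_svp_nucleus").strip().lower()
        if enl_raw == "":
            enl = None
        elif enl_raw in _TRUE_STRINGS:
            enl = True
        elif enl_raw in _FALSE_STRINGS:
            enl = False
        else:
            raise ValueError(f"line {line}: bad enlarged_svp_nucleus {enl_raw!r}")
        rec = CellCountRecord(
            embryo_id=getattr(row, "embryo_id"),
            genotype=getattr(row, "genotype"),
            segment=segment,
            side=side,
            tin_cc=_parse_int(getattr(row, "tin_cc").strip(), "tin_cc", line),
            svp_cc=_parse_int(getattr(row, "svp_cc").strip(), "svp_cc", line),
            svp_pc=svp_pc,
            enlarged_svp_nucleus=enl,
            assay=row_assay,
        )
        rec.validate()
        records.append(rec)
    return records


def format_percent(pct: float) -> str:
    """Percentages to one decimal place ("17.9" style)."""
    return f"{pct:.1f}"


def format_pvalue(p: float) -> str:
    """p-values to 4 decimals with a "<0.0001" floor."""
    if p < 0.0001:
        return "<0.0001"
    return f"{p:.4f}"


ROLES = (ROLE_CONTROL, ROLE_SINGLE_1, ROLE_SINGLE_2, ROLE_DOUBLE,
         ROLE_WILDTYPE, ROLE_MUTANT)


@dataclass
class RunConfig:
    """End-to-end pipeline settings.

    ``roles`` maps every genotype in the input to its analysis role:
    wildtype/mutant for a two-group run, or control/single_het_1/
    single_het_2/double_het for an interaction (synergy) run. The test to
    run is inferred from which roles are present.
    """

    inputs: Sequence[str | Path]
    roles: dict[str, str]
    out_dir: str | Path = "out"
    assay: str | None = None
    categories: Sequence[str] | None = None
    perm: PermutationConfig = field(default_factory=PermutationConfig)
    with_intercept: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for g, r in self.roles.items():
            if r not in ROLES:
                raise ValueError(f"genotype {g!r} has unknown role {r!r}")


def _derive_seed(seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_pipeline(config: RunConfig) -> dict:
    """Read → classify → summarize → test → report.

    Writes ``embryo_summaries.csv``, ``genotype_report.csv`` and
    ``tests.json`` under ``out_dir``; deterministic given (inputs, config,
    seed). Returns the in-memory tables and test results.
    """
    configure_logging(config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records: list[CellCountRecord] = []
    for p in config.inputs:
        records.extend(read_counts(p, assay=config.assay))
    frame = records_to_frame(records)
    assay = frame["assay"].iloc[0]
    if (frame["assay"] != assay).any():
        raise ValueError("mixed assay modes across inputs")

    genotypes = sorted(frame["genotype"].unique())
    uncovered = [g for g in genotypes if g not in config.roles]
    if uncovered:
        raise ValueError(f"genotypes without a role: {uncovered}")

    summary = summarize_table(frame)
    summary_path = out_dir / "embryo_summaries.csv"
    summary.to_csv(summary_path, index=False)

    agg = aggregate_genotype(summary)
    categories = tuple(config.categories or categories_for_assay(assay))

    roleset = set(config.roles.values())
    if {ROLE_SINGLE_1, ROLE_SINGLE_2, ROLE_DOUBLE} <= roleset:
        test_kind = "interaction"
    elif {ROLE_WILDTYPE, ROLE_MUTANT} <= roleset:
        test_kind = "two_group"
    else:
        raise ValueError(
            "roles must include wildtype+mutant (two-group) or "
            "single_het_1+single_het_2+double_het (interaction)"
        )
    by_role: dict[str, str] = {r: g for g, r in config.roles.items()}
    logger.info(
        "test=%s N=%d seed=%d tie_rule=%s tail=%s alpha=%g with_intercept=%s",
        test_kind, config.perm.n_permutations, config.perm.seed,
        config.perm.tie_rule, config.perm.tail, config.perm.alpha,
        config.with_intercept,
    )

    tests: dict[str, dict] = {}
    for k, cat in enumerate(categories):
        seed_cat = _derive_seed(config.perm.seed, k)
        pconf = replace(config.perm, seed=seed_cat)
        if test_kind == "interaction":
            s = ProportionSample.interaction(
                summary, cat, config.roles,
                include_control=config.with_intercept and ROLE_CONTROL in roleset,
            )
            res = interaction_perm_test(s, pconf, with_intercept=config.with_intercept)
            entry = res.to_dict()
            entry["synergy_call"] = synergy_call(res, config.perm.alpha)
        else:
            s = ProportionSample.two_group(
                summary, cat, group1=by_role[ROLE_MUTANT], group0=by_role[ROLE_WILDTYPE]
            )
            res = two_group_perm_test(s, pconf)
            entry = res.to_dict()
        entry["category"] = cat
        entry["p_value_formatted"] = format_pvalue(res.p_value)
        tests[cat] = entry
        logger.info(
            "%s %s: coefficient=%.6f p=%s (n=%d, N=%d, exhaustive=%s)",
            test_kind, cat, res.coefficient, format_pvalue(res.p_value),
            res.exceedances, res.n_permutations, res.exhaustive,
        )

    report = agg[agg["category"].isin(categories + (UNCLASSIFIED_SVP,))].copy()
    report["pooled_pct_formatted"] = report["pooled_pct"].map(format_percent)
    report["p_value"] = ""
    report["expected_additive_pct"] = np.nan
    focus = by_role[ROLE_DOUBLE] if test_kind == "interaction" else by_role[ROLE_MUTANT]
    for cat, entry in tests.items():
        mask = (report["genotype"] == focus) & (report["category"] == cat)
        report.loc[mask, "p_value"] = entry["p_value_formatted"]
        if test_kind == "interaction":
            # the "dashed line": additive sum of the two single-het percentages
            add = sum(
                float(report.loc[
                    (report["genotype"] == by_role[role]) & (report["category"] == cat),
                    "pooled_pct",
                ].iloc[0])
                for role in (ROLE_SINGLE_1, ROLE_SINGLE_2)
            )
            report.loc[mask, "expected_additive_pct"] = add
    report_path = out_dir / "genotype_report.csv"
    report.to_csv(report_path, index=False)

    tests_path = out_dir / "tests.json"
    with open(tests_path, "w") as fh:
        json.dump(tests, fh, indent=2, sort_keys=True)

    return {
        "summary": summary,
        "report": report,
        "tests": tests,
        "paths": {
            "summary": summary_path, "report": report_path, "tests": tests_path,
        },
    }
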