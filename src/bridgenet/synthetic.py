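"""Synthetic mixed ordinal/Gaussian data with known graph structure.

The generator draws from a pairwise Markov random field whose node
conditionals are exponential-family: multinomial for ordinal symptom items,
Gaussian for metabolite concentrations (on the post-log scale).  The joint
log-density is, up to a constant,

    f(x) = sum_cat  theta_i[x_i]
         + sum_cont ( alpha_i x_i / s_i^2  -  x_i^2 / (2 s_i^2) )
         + sum_{i<j} pairwise(i, j)

with pairwise terms ``c * x_i * x_j`` (continuous-continuous),
``rho[x_i] * x_j`` (categorical-continuous) and ``M[x_i, x_j]``
(categorical-categorical).  Under this convention a positive coupling ``c``
between continuous nodes contributes ``+ s_i^2 * c * x_j`` to node i's
conditional mean, so positive couplings produce positive marginal
correlations and the implied joint-Gaussian precision off-diagonal is
``-c``.

Sampling uses many independent Gibbs chains run in parallel (vectorised
across chains); ``burn_in`` sweeps are discarded per chain and successive
draws from the same chain are separated by ``thin`` sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .variables import (
    CATEGORICAL,
    CONTINUOUS,
    COVARIATE_COLUMNS,
    MOOD_COGNITION,
    SOMATIC,
    CovariateTable,
    MixedDataMatrix,
    NumericalError,
    ParameterError,
    SpecificationError,
    VariableSpec,
)

__all__ = [
    "PairwiseMixedModel",
    "CovariateModel",
    "gibbs_sample",
    "apply_covariates",
    "inject_missing",
    "demo_model",
    "demo_covariate_model",
    "demo_missing_rates",
    "null_scenario",
    "confounded_scenario",
    "generate_dataset",
    "model_to_yaml",
    "model_from_yaml",
]


# ---------------------------------------------------------------------------
# ground-truth model
# ---------------------------------------------------------------------------


@dataclass
class PairwiseMixedModel:
    """Ground-truth parameters of the pairwise mixed MRF.

    ``couplings`` is keyed by ordered node-name pairs ``(i, j)`` with
    ``index(i) < index(j)``; blocks are oriented accordingly (rows belong to
    the lower-index node).  Pairs absent from the map carry an implicit
    all-zero block.  Categorical blocks follow the reference-level
    convention: any entry indexed by level 0 is zero.
    """

    node_specs: list[VariableSpec]
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    variances: dict[str, float] = field(default_factory=dict)
    couplings: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    bridge_set: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        self._index = {s.name: k for k, s in enumerate(self.node_specs)}
        for s in self.node_specs:
            if s.is_categorical:
                self.thresholds.setdefault(s.name, np.zeros(s.n_levels))
                self.thresholds[s.name] = np.asarray(self.thresholds[s.name], float)
            else:
                self.means.setdefault(s.name, 0.0)
                self.variances.setdefault(s.name, 1.0)
        self.couplings = {
            self._canonical_key(*k): self._orient(k, np.asarray(v, float))
            for k, v in self.couplings.items()
        }

    # -- key handling ----------------------------------------------------
    def _canonical_key(self, a: str, b: str) -> tuple[str, str]:
        if a not in self._index or b not in self._index:
            raise SpecificationError(f"unknown node in pair ({a}, {b})")
        if a == b:
            raise SpecificationError(f"self-coupling on {a!r}")
        return (a, b) if self._index[a] < self._index[b] else (b, a)

    def _orient(self, key, block):
        a, b = key
        if self._index[a] < self._index[b]:
            return block
        return block.T if block.ndim == 2 else block

    def spec(self, name: str) -> VariableSpec:
        return self.node_specs[self._index[name]]

    def block(self, a: str, b: str) -> np.ndarray:
        """Coupling block oriented so the first axis belongs to ``a``."""
        key = self._canonical_key(a, b)
        blk = self.couplings.get(key)
        if blk is None:
            sa, sb = self.spec(a), self.spec(b)
            ra = (sa.n_levels,) if sa.is_categorical else ()
            rb = (sb.n_levels,) if sb.is_categorical else ()
            blk = np.zeros(ra + rb) if (ra or rb) else np.zeros(())
            return blk
        return blk if key == (a, b) else (blk.T if blk.ndim == 2 else blk)

    def set_coupling(self, a: str, b: str, block, bridge: bool = False) -> None:
        key = self._canonical_key(a, b)
        blk = np.asarray(block, float)
        self.couplings[key] = blk if key == (a, b) else (blk.T if blk.ndim == 2 else blk)
        if bridge:
            self.bridge_set.add(key)

    def neighbors(self, name: str) -> list[str]:
        out = []
        for (a, b) in self.couplings:
            if a == name:
                out.append(b)
            elif b == name:
                out.append(a)
        return out

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for s in self.node_specs:
            if s.is_categorical:
                th = self.thresholds[s.name]
                if th.shape != (s.n_levels,):
                    raise ParameterError(f"thresholds for {s.name!r} have wrong length")
            else:
                if not self.variances[s.name] > 0:
                    raise ParameterError(f"non-positive variance on {s.name!r}")
        for (a, b), blk in self.couplings.items():
            sa, sb = self.spec(a), self.spec(b)
            exp_shape = ()
            if sa.is_categorical:
                exp_shape += (sa.n_levels,)
            if sb.is_categorical:
                exp_shape += (sb.n_levels,)
            if blk.shape != exp_shape:
                raise ParameterError(f"coupling block ({a}, {b}) has shape {blk.shape}")
            if sa.is_categorical and not np.allclose(np.take(blk, 0, axis=0), 0):
                raise ParameterError(f"block ({a}, {b}): reference level of {a!r} not zero")
            if sb.is_categorical and blk.ndim == 2 and not np.allclose(blk[:, 0], 0):
                raise ParameterError(f"block ({a}, {b}): reference level of {b!r} not zero")
            if not np.all(np.isfinite(blk)):
                raise ParameterError(f"non-finite coupling block ({a}, {b})")
        prec = self.continuous_precision()
        if prec.size:
            eig = np.linalg.eigvalsh(prec)
            if eig.min() <= 0:
                raise ParameterError(
                    "continuous-part precision matrix is not positive definite "
                    f"(min eigenvalue {eig.min():.4f})"
                )

    def continuous_precision(self) -> np.ndarray:
        """Precision matrix of the Gaussian nodes given the categorical ones."""
        cont = [s.name for s in self.node_specs if not s.is_categorical]
        pos = {n: k for k, n in enumerate(cont)}
        prec = np.zeros((len(cont), len(cont)))
        for n in cont:
            prec[pos[n], pos[n]] = 1.0 / self.variances[n]
        for (a, b), blk in self.couplings.items():
            if a in pos and b in pos:
                prec[pos[a], pos[b]] = prec[pos[b], pos[a]] = -float(blk)
        return prec


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def gibbs_sample(
    model: PairwiseMixedModel,
    n: int,
    burn_in: int = 500,
    thin: int = 2,
    seed: int = 0,
    chains: int | None = None,
) -> MixedDataMatrix:
    """Draw ``n`` rows from the MRF by parallel-chain Gibbs sampling.

    Each of ``chains`` independent chains is swept ``burn_in`` times, then
    sampled every ``thin`` sweeps until ``n`` rows are collected.  Identical
    seeds give identical output.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if burn_in < 0 or thin < 1:
        raise ParameterError("burn_in must be >= 0 and thin >= 1")
    model.validate()
    rng = np.random.default_rng(seed)
    specs = model.node_specs
    p = len(specs)
    C = min(n, 256) if chains is None else int(chains)
    m = math.ceil(n / C)

    # initial state
    state = np.empty((C, p))
    for j, s in enumerate(specs):
        if s.is_categorical:
            state[:, j] = rng.integers(s.n_levels, size=C)
        else:
            state[:, j] = model.means[s.name] + math.sqrt(
                model.variances[s.name]
            ) * rng.standard_normal(C)

    # per-node neighbor structure, resolved to column indices once
    idx = {s.name: j for j, s in enumerate(specs)}
    neigh: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(p)]
    for (a, b), _ in model.couplings.items():
        ja, jb = idx[a], idx[b]
        neigh[ja].append((jb, model.block(a, b)))
        neigh[jb].append((ja, model.block(b, a)))

    def sweep():
        for j, s in enumerate(specs):
            if s.is_categorical:
                scores = np.tile(model.thresholds[s.name], (C, 1))
                for k, blk in neigh[j]:
                    if specs[k].is_categorical:
                        scores += blk[:, state[:, k].astype(int)].T
                    else:
                        scores += np.outer(state[:, k], blk)
                if not np.all(np.isfinite(scores)):
                    raise NumericalError(f"non-finite conditional score at node {s.name!r}")
                g = rng.gumbel(size=scores.shape)
                state[:, j] = np.argmax(scores + g, axis=1)
            else:
                var = model.variances[s.name]
                mean = np.full(C, model.means[s.name])
                for k, blk in neigh[j]:
                    if specs[k].is_categorical:
                        mean += var * blk[state[:, k].astype(int)]
                    else:
                        mean += var * float(blk) * state[:, k]
                if not np.all(np.isfinite(mean)):
                    raise NumericalError(f"non-finite conditional mean at node {s.name!r}")
                state[:, j] = mean + math.sqrt(var) * rng.standard_normal(C)

    for _ in range(burn_in):
        sweep()
    records = [state.copy()]
    for _ in range(m - 1):
        for _ in range(thin):
            sweep()
        records.append(state.copy())
    values = np.vstack(records)[:n]
    return MixedDataMatrix(values, list(specs))


# ---------------------------------------------------------------------------
# covariates and missingness
# ---------------------------------------------------------------------------

# marginal distributions used to draw covariates; binary covariates are
# Bernoulli, age/BMI Gaussian (roughly adult-outpatient-cohort shaped)
_COVARIATE_DISTS = {
    "sex": ("bernoulli", 0.66),
    "age": ("normal", 42.0, 13.0),
    "batch": ("bernoulli", 0.5),
    "bmi": ("normal", 25.6, 4.8),
    "smoking": ("bernoulli", 0.38),
    "ad_use": ("bernoulli", 0.22),
    "statin_use": ("bernoulli", 0.08),
}


@dataclass
class CovariateModel:
    """Additive covariate effects on generated variables.

    ``effects`` maps a covariate name to ``(target variable, effect size)``
    pairs.  Binary covariates act through their raw 0/1 indicator;
    continuous covariates (age, BMI) are standardised before the effect is
    applied.  Effects on categorical targets shift a uniform-dequantised
    latent copy of the level, which is then re-floored into ``0..L-1``.
    """

    effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    batch_sensitive_set: set[str] = field(default_factory=set)

    def validate(self, data: MixedDataMatrix) -> None:
        for cov, pairs in self.effects.items():
            if cov not in COVARIATE_COLUMNS:
                raise SpecificationError(f"unknown covariate {cov!r}")
            for target, eff in pairs:
                if target not in data.names:
                    raise SpecificationError(f"unknown target variable {target!r}")
                if not np.isfinite(eff):
                    raise ParameterError(f"non-finite effect for {cov}->{target}")
        for m in self.batch_sensitive_set:
            if m not in data.continuous_names:
                raise SpecificationError(
                    f"batch-sensitive variable {m!r} is not a continuous column"
                )


def draw_covariates(n: int, seed: int) -> CovariateTable:
    rng = np.random.default_rng(seed)
    cols = {}
    for name in COVARIATE_COLUMNS:
        dist = _COVARIATE_DISTS[name]
        if dist[0] == "bernoulli":
            cols[name] = rng.binomial(1, dist[1], size=n).astype(float)
        else:
            cols[name] = dist[1] + dist[2] * rng.standard_normal(n)
    return CovariateTable(pd.DataFrame(cols))


def _covariate_signal(table: CovariateTable, name: str) -> np.ndarray:
    x = table.frame[name].to_numpy(dtype=float)
    dist = _COVARIATE_DISTS[name]
    if dist[0] == "normal":
        return (x - dist[1]) / dist[2]
    return x


def apply_covariates(
    data: MixedDataMatrix, cov_model: CovariateModel, seed: int
) -> tuple[MixedDataMatrix, CovariateTable]:
    """Draw a covariate table and push its effects into the data.

    Continuous targets receive the effect additively; categorical targets
    are dequantised (level + U[0,1)), shifted on that latent scale, and
    re-floored.  An empty effects map returns the data unchanged.
    """
    cov_model.validate(data)
    table = draw_covariates(data.n, seed)
    out = data.copy()
    if not cov_model.effects:
        return out, table
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    # accumulate per-target shifts so multiple covariates compose additively
    shifts = np.zeros_like(out.values)
    for cov, pairs in cov_model.effects.items():
        z = _covariate_signal(table, cov)
        for target, eff in pairs:
            shifts[:, out.column_index(target)] += eff * z
    for j, s in enumerate(out.specs):
        sh = shifts[:, j]
        if not np.any(sh):
            continue
        col = out.values[:, j]
        if s.is_categorical:
            latent = col + rng.uniform(0.0, 1.0, size=out.n)
            out.values[:, j] = np.clip(np.floor(latent + sh), 0, s.n_levels - 1)
        else:
            out.values[:, j] = col + sh
    return out, table


def inject_missing(
    data: MixedDataMatrix, column_rates: dict[str, float], seed: int
) -> MixedDataMatrix:
    """Set cells missing completely at random at per-column rates."""
    for name, rate in column_rates.items():
        if not 0 <= rate < 1:
            raise ParameterError(f"missing rate for {name!r} must be in [0, 1)")
        if name not in data.names:
            raise SpecificationError(f"unknown variable {name!r}")
    rng = np.random.default_rng(seed)
    out = data.copy()
    for name, rate in column_rates.items():
        if rate == 0:
            continue
        j = out.column_index(name)
        mask = rng.random(out.n) < rate
        out.values[mask, j] = np.nan
    return out


# ---------------------------------------------------------------------------
# bundled scenarios
# ---------------------------------------------------------------------------

_SOMATIC_ITEMS = [
    "falling_asleep", "night_waking", "early_waking", "hypersomnia",
    "appetite_decrease", "appetite_increase", "weight_decrease",
    "weight_increase", "fatigue", "aches_pains", "leaden_paralysis",
    "gastrointestinal", "panic_symptoms",
]
_MOOD_ITEMS = [
    "sad_mood", "irritability", "anxious_mood", "mood_reactivity",
    "quality_of_mood", "concentration", "self_criticism",
    "suicidal_thoughts", "general_interest", "pleasure_enjoyment",
    "interest_in_sex", "psychomotor_slowing", "psychomotor_agitation",
    "interpersonal_sensitivity", "future_pessimism", "crying",
]
_OTHER_ITEMS = ["diurnal_variation"]

_METABOLITE_SUBCLASSES = {
    "amino_acids": ["alanine", "glutamine", "glycine", "histidine",
                    "isoleucine", "leucine", "valine", "phenylalanine", "tyrosine"],
    "apolipoproteins": ["apoa1", "apob"],
    "cholesterol": ["total_c", "ldl_c", "hdl_c", "hdl2_c", "hdl3_c",
                    "esterified_c", "remnant_c"],
    "fatty_acids": ["dha", "linoleic_acid", "omega3", "omega6", "mufa", "pufa", "sfa"],
    "glycerides_phospholipids": ["total_tg", "vldl_tg", "ldl_tg", "hdl_tg",
                                 "phosphoglycerides", "phosphatidylcholine",
                                 "sphingomyelins"],
    "particle_size": ["vldl_d", "ldl_d", "hdl_d"],
    "saturation": ["unsaturation"],
    "fluid_balance": ["albumin", "creatinine"],
    "glycolysis": ["glucose", "lactate", "pyruvate", "citrate", "glycerol"],
    "inflammation": ["glyca"],
    "ketone_bodies": ["acetoacetate", "bhb"],
}

#: level-0-referenced skewed thresholds for 4-level ordinal items
_SYMPTOM_THRESHOLDS = np.array([0.0, -0.4, -1.0, -1.8])

#: planted symptom-metabolite couplings in the study-shaped demo scenario
DEMO_BRIDGES = [
    ("fatigue", "vldl_d", +0.35),
    ("fatigue", "unsaturation", -0.35),
    ("hypersomnia", "histidine", -0.35),
    ("weight_increase", "glucose", +0.35),
    ("self_criticism", "acetoacetate", +0.35),
]

#: metabolites receiving an additive batch shift in the demo scenario
DEMO_BATCH_SENSITIVE = [
    "alanine", "glutamine", "histidine", "total_c", "ldl_c", "dha",
    "total_tg", "vldl_d", "glucose", "lactate", "citrate", "glyca", "bhb",
]


def _ordinal_block(levels_a: int, levels_b: int, w: float) -> np.ndarray:
    """Level-product interaction (reference levels automatically zero)."""
    la = np.arange(levels_a) / (levels_a - 1)
    lb = np.arange(levels_b) / (levels_b - 1)
    return w * np.outer(la, lb)


def demo_specs() -> list[VariableSpec]:
    specs = []
    k = 0
    for name in _SOMATIC_ITEMS:
        specs.append(VariableSpec(name, CATEGORICAL, 4, SOMATIC, k)); k += 1
    for name in _MOOD_ITEMS:
        specs.append(VariableSpec(name, CATEGORICAL, 4, MOOD_COGNITION, k)); k += 1
    for name in _OTHER_ITEMS:
        specs.append(VariableSpec(name, CATEGORICAL, 4, "ungrouped", k)); k += 1
    for subclass, names in _METABOLITE_SUBCLASSES.items():
        for name in names:
            specs.append(VariableSpec(name, CONTINUOUS, 0, subclass, k)); k += 1
    return specs


def demo_model() -> PairwiseMixedModel:
    """Study-shaped scenario: 30 ordinal items, 46 metabolites, 5 bridges.

    Within-group dependence is banded (chain plus second-neighbour
    couplings) and far stronger than cross-group dependence, which consists
    solely of the five planted bridges.
    """
    specs = demo_specs()
    model = PairwiseMixedModel(
        node_specs=specs,
        thresholds={s.name: _SYMPTOM_THRESHOLDS.copy() for s in specs if s.is_categorical},
        means={s.name: 1.0 for s in specs if not s.is_categorical},
        variances={s.name: 0.36 for s in specs if not s.is_categorical},
    )
    symptoms = [s.name for s in specs if s.is_categorical]
    for i in range(len(symptoms) - 1):
        model.set_coupling(symptoms[i], symptoms[i + 1], _ordinal_block(4, 4, 1.2))
    for i in range(len(symptoms) - 2):
        model.set_coupling(symptoms[i], symptoms[i + 2], _ordinal_block(4, 4, 0.6))
    for names in _METABOLITE_SUBCLASSES.values():
        for i in range(len(names) - 1):
            model.set_coupling(names[i], names[i + 1], 0.7)
        for i in range(len(names) - 2):
            model.set_coupling(names[i], names[i + 2], 0.35)
    # weak chain linking subclass heads keeps the metabolite block connected
    heads = [names[0] for names in _METABOLITE_SUBCLASSES.values()]
    for i in range(len(heads) - 1):
        model.set_coupling(heads[i], heads[i + 1], 0.25)
    for symptom, metabolite, slope in DEMO_BRIDGES:
        model.set_coupling(
            symptom, metabolite, slope * np.arange(4), bridge=True
        )
    model.validate()
    return model


def demo_covariate_model() -> CovariateModel:
    """Batch shifts on 13 metabolites plus a BMI confounder and small
    lifestyle/medication effects."""
    effects = {
        "batch": [(m, 0.3) for m in DEMO_BATCH_SENSITIVE],
        "bmi": [("total_tg", 0.3), ("appetite_increase", 0.35)],
        "age": [("glucose", 0.15)],
        "sex": [("creatinine", -0.2)],
        "smoking": [("glyca", 0.2)],
        "statin_use": [("ldl_c", -0.4)],
        "ad_use": [("weight_increase", 0.2)],
    }
    return CovariateModel(effects=effects, batch_sensitive_set=set(DEMO_BATCH_SENSITIVE))


def demo_missing_rates() -> dict[str, float]:
    """MCAR rates low enough to keep all 46 metabolite columns (row loss
    only, a few percent of subjects)."""
    targets = ["glycine", "tyrosine", "remnant_c", "sphingomyelins", "pyruvate", "bhb"]
    return {m: 0.005 for m in targets}


def null_scenario(n_cat: int = 5, n_cont: int = 7) -> PairwiseMixedModel:
    """Reduced scenario with zero cross-group coupling (type-I error runs)."""
    specs = []
    for i in range(n_cat):
        specs.append(VariableSpec(f"sym{i}", CATEGORICAL, 4, SOMATIC, i))
    for i in range(n_cont):
        specs.append(VariableSpec(f"met{i}", CONTINUOUS, 0, "panel", n_cat + i))
    model = PairwiseMixedModel(
        node_specs=specs,
        thresholds={s.name: _SYMPTOM_THRESHOLDS.copy() for s in specs if s.is_categorical},
        variances={s.name: 1.0 for s in specs if not s.is_categorical},
    )
    for i in range(n_cat - 1):
        model.set_coupling(f"sym{i}", f"sym{i+1}", _ordinal_block(4, 4, 1.2))
    for i in range(n_cont - 1):
        model.set_coupling(f"met{i}", f"met{i+1}", 0.3)
    model.validate()
    return model


def small_scenario() -> PairwiseMixedModel:
    """Compact mixed scenario (6 symptoms, 8 metabolites, 2 bridges) for
    fast end-to-end runs."""
    specs = []
    soma = ["hypersomnia", "fatigue", "appetite_increase"]
    mood = ["sad_mood", "concentration", "self_criticism"]
    mets = {"amino_acids": ["histidine", "glycine", "alanine", "glutamine"],
            "glycolysis": ["glucose", "citrate", "lactate", "pyruvate"]}
    k = 0
    for name in soma:
        specs.append(VariableSpec(name, CATEGORICAL, 4, SOMATIC, k)); k += 1
    for name in mood:
        specs.append(VariableSpec(name, CATEGORICAL, 4, MOOD_COGNITION, k)); k += 1
    for subclass, names in mets.items():
        for name in names:
            specs.append(VariableSpec(name, CONTINUOUS, 0, subclass, k)); k += 1
    model = PairwiseMixedModel(
        node_specs=specs,
        thresholds={s.name: _SYMPTOM_THRESHOLDS.copy() for s in specs if s.is_categorical},
        variances={s.name: 1.0 for s in specs if not s.is_categorical},
    )
    symptoms = soma + mood
    for i in range(len(symptoms) - 1):
        model.set_coupling(symptoms[i], symptoms[i + 1], _ordinal_block(4, 4, 1.2))
    for names in mets.values():
        for i in range(len(names) - 1):
            model.set_coupling(names[i], names[i + 1], 0.3)
    model.set_coupling("fatigue", "glucose", 0.4 * np.arange(4), bridge=True)
    model.set_coupling("hypersomnia", "histidine", -0.4 * np.arange(4), bridge=True)
    model.validate()
    return model


def confounded_scenario() -> tuple[PairwiseMixedModel, CovariateModel]:
    """One symptom and one metabolite driven by a BMI-like covariate with no
    direct coupling between them."""
    specs = [
        VariableSpec("fatigue", CATEGORICAL, 4, SOMATIC, 0),
        VariableSpec("sad_mood", CATEGORICAL, 4, MOOD_COGNITION, 1),
        VariableSpec("total_tg", CONTINUOUS, 0, "glycerides_phospholipids", 2),
        VariableSpec("hdl_c", CONTINUOUS, 0, "cholesterol", 3),
    ]
    model = PairwiseMixedModel(
        node_specs=specs,
        thresholds={"fatigue": _SYMPTOM_THRESHOLDS.copy(),
                    "sad_mood": _SYMPTOM_THRESHOLDS.copy()},
        variances={"total_tg": 1.0, "hdl_c": 1.0},
    )
    model.set_coupling("fatigue", "sad_mood", _ordinal_block(4, 4, 1.0))
    model.set_coupling("total_tg", "hdl_c", -0.3)
    model.validate()
    cov = CovariateModel(effects={"bmi": [("fatigue", 0.6), ("total_tg", 0.6)]})
    return model, cov


def generate_dataset(
    model: PairwiseMixedModel,
    cov_model: CovariateModel | None,
    n: int,
    seed: int,
    missing_rates: dict[str, float] | None = None,
    burn_in: int = 500,
    thin: int = 2,
) -> tuple[MixedDataMatrix, CovariateTable]:
    """Sample the MRF, apply covariate effects, then inject missingness.

    Seeds for the three stages are fanned out from ``seed`` via a
    :class:`numpy.random.SeedSequence`, so a single integer reproduces the
    full dataset.
    """
    s_gibbs, s_cov, s_miss = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    data = gibbs_sample(model, n, burn_in=burn_in, thin=thin, seed=int(s_gibbs))
    if cov_model is None:
        cov_model = CovariateModel()
    data, table = apply_covariates(data, cov_model, int(s_cov))
    if missing_rates:
        data = inject_missing(data, missing_rates, int(s_miss))
    return data, table


def to_concentration_scale(data: MixedDataMatrix) -> MixedDataMatrix:
    """Map metabolite columns from the model's post-log scale to raw
    concentrations via expm1, so the preprocessing ln(1+x) transform
    recovers the modelled values exactly."""
    out = data.copy()
    for j, s in enumerate(out.specs):
        if s.is_metabolite:
            out.values[:, j] = np.expm1(out.values[:, j])
    return out


# ---------------------------------------------------------------------------
# serialization of the ground truth
# ---------------------------------------------------------------------------


def model_to_yaml(model: PairwiseMixedModel) -> str:
    doc = {
        "nodes": [
            {"name": s.name, "kind": s.kind, "n_levels": s.n_levels,
             "group": s.group, "index": s.index}
            for s in model.node_specs
        ],
        "thresholds": {k: v.tolist() for k, v in model.thresholds.items()},
        "means": dict(model.means),
        "variances": dict(model.variances),
        "couplings": [
            {"i": a, "j": b, "block": blk.tolist()}
            for (a, b), blk in sorted(model.couplings.items())
        ],
        "bridges": sorted(list(b) for b in model.bridge_set),
    }
    return yaml.safe_dump(doc, sort_keys=False)


def model_from_yaml(text: str) -> PairwiseMixedModel:
    doc = yaml.safe_load(text)
    specs = [VariableSpec(**d) for d in doc["nodes"]]
    model = PairwiseMixedModel(
        node_specs=specs,
        thresholds={k: np.asarray(v, float) for k, v in doc["thresholds"].items()},
        means={k: float(v) for k, v in doc["means"].items()},
        variances={k: float(v) for k, v in doc["variances"].items()},
        couplings={(c["i"], c["j"]): np.asarray(c["block"], float)
                   for c in doc["couplings"]},
        bridge_set={tuple(b) for b in doc["bridges"]},
    )
    model.validate()
    return model
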