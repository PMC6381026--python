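"""Monte-Carlo study of the necessity permutation test's power and type-I error.

Three experiment sets probe how often the permutation test of the CE-FDH
necessity effect is significant (p < alpha) as a function of the true
population necessity effect, the true population sufficiency effect, and
the sample size:

* **Set 1 — without sufficiency.**  l fixed at 1 (true sufficiency 0);
  u and the per-level sample size vary.  Measures power as a function of
  true necessity and N, and type-I error at u = 9.
* **Set 2 — with sufficiency.**  Sample size fixed at N = 45 (n_per_x = 5);
  u and l vary.  Shows how sufficiency shifts significance at small N.
* **Set 3 — without necessity.**  u fixed at 9 (true necessity 0); l and N
  vary.  Isolates the type-I error rate as a function of sufficiency —
  the paradox that significance *rises* with sufficiency.

Where a parameter varies, it is drawn uniformly over its admissible grid
(u, l in 1..9; n_per_x in 2..55) independently across replicates.

Per-replicate outcomes are summarized by a logistic regression of the
significance indicator on a subset of {true necessity, true sufficiency,
sqrt(N)}; the inverse-logit of the fitted linear predictor is the
predicted power surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from ._exceptions import SeparationWarning, ValidationError
from .permutation import permutation_test
from .population import (
    PopulationSpec,
    sample_population,
    true_necessity_effect,
    true_sufficiency_effect,
)

__all__ = [
    "ExperimentConfig",
    "SimulationRecord",
    "PowerModel",
    "run_replicate",
    "run_experiment_set",
    "fit_power_model",
    "predict_power",
    "summarize_rejection_rates",
]

logger = logging.getLogger(__name__)

#: admissible grids for parameters that vary across replicates
U_GRID = tuple(range(1, 10))
L_GRID = tuple(range(1, 10))
N_PER_X_GRID = tuple(range(2, 56))  # N = 18 .. 495

PREDICTOR_NAMES = ("true_necessity", "true_sufficiency", "sqrt_N")

RECORD_COLUMNS = [
    "replicate_id", "u", "l", "n_per_x", "N",
    "true_necessity", "true_sufficiency",
    "observed_effect", "p_value", "significant", "seed",
]


@dataclass(frozen=True)
class SimulationRecord:
    """Outcome of one simulated sample-and-test replicate."""

    replicate_id: int
    u: int
    l: int
    n_per_x: int
    N: int
    true_necessity: float
    true_sufficiency: float
    observed_effect: float
    p_value: float
    significant: bool
    seed: int


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one experiment set.

    ``u``, ``l`` and ``n_per_x`` are either a fixed integer or ``None``,
    meaning "draw uniformly from the grid per replicate".
    """

    set_id: int
    n_replicates: int
    n_permutations: int = 1000
    alpha: float = 0.05
    u: int | None = None
    l: int | None = None
    n_per_x: int | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.set_id not in (1, 2, 3):
            raise ValidationError(f"set_id must be 1, 2 or 3, got {self.set_id}")
        if self.n_replicates < 1 or self.n_permutations < 1:
            raise ValidationError("replicate and permutation counts must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def for_set(
        cls,
        set_id: int,
        n_replicates: int | None = None,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        master_seed: int = 0,
    ) -> "ExperimentConfig":
        """Canonical design for one of the three experiment sets.

        Default replicate counts follow the study design: 2000 for sets 1
        and 2, 500 for set 3.
        """
        defaults = {1: 2000, 2: 2000, 3: 500}
        fixed = {1: {"l": 1}, 2: {"n_per_x": 5}, 3: {"u": 9}}
        if set_id not in defaults:
            raise ValidationError(f"set_id must be 1, 2 or 3, got {set_id}")
        return cls(
            set_id=set_id,
            n_replicates=n_replicates if n_replicates is not None else defaults[set_id],
            n_permutations=n_permutations,
            alpha=alpha,
            master_seed=master_seed,
            **fixed[set_id],
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ExperimentConfig":
        """Build a config from a plain key/value mapping (e.g. parsed YAML)."""
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


def _derive_seed(ss: np.random.SeedSequence) -> int:
    # single 31-bit integer so records stay portable
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_replicate(
    u: int,
    l: int,
    n_per_x: int,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    replicate_id: int = 0,
) -> SimulationRecord:
    """Sample one population, run the permutation test, flag significance.

    Fully deterministic given ``seed``: the sample and the reshuffles are
    drawn from a single generator stream.
    """
    spec = PopulationSpec(u=u, l=l)
    rng = np.random.default_rng(seed)
    data = sample_population(spec, n_per_x, seed=rng)
    result = permutation_test(data, n_permutations=n_permutations, seed=rng)
    return SimulationRecord(
        replicate_id=replicate_id,
        u=u,
        l=l,
        n_per_x=n_per_x,
        N=9 * n_per_x,
        true_necessity=spec.true_necessity,
        true_sufficiency=spec.true_sufficiency,
        observed_effect=result.observed_effect,
        p_value=result.p_value,
        significant=bool(result.p_value < alpha),
        seed=seed if seed is not None else -1,
    )


def run_experiment_set(
    config: ExperimentConfig,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Run all replicates of an experiment set.

    Per-replicate parameters are drawn by the set's policies from a
    parameter stream spawned off ``master_seed``; each replicate then gets
    its own derived integer seed, so individual records can be reproduced
    with :func:`run_replicate` alone.  If ``out_path`` is given, records are
    appended to a CSV as they are produced.
    """
    root = np.random.SeedSequence(config.master_seed)
    param_ss, *rep_ss = root.spawn(config.n_replicates + 1)
    param_rng = np.random.default_rng(param_ss)

    out_file = None
    if out_path is not None:
        out_file = open(out_path, "w", encoding="utf-8")
        out_file.write(",".join(RECORD_COLUMNS) + "\n")

    records: list[SimulationRecord] = []
    try:
        for i in range(config.n_replicates):
            u = config.u if config.u is not None else int(param_rng.choice(U_GRID))
            l = config.l if config.l is not None else int(param_rng.choice(L_GRID))
            n_per_x = (
                config.n_per_x
                if config.n_per_x is not None
                else int(param_rng.choice(N_PER_X_GRID))
            )
            rec = run_replicate(
                u=u,
                l=l,
                n_per_x=n_per_x,
                n_permutations=config.n_permutations,
                alpha=config.alpha,
                seed=_derive_seed(rep_ss[i]),
                replicate_id=i,
            )
            records.append(rec)
            if out_file is not None:
                row = asdict(rec)
                out_file.write(
                    ",".join(repr(row[c]) if isinstance(row[c], float) else str(row[c])
                             for c in RECORD_COLUMNS) + "\n"
                )
    finally:
        if out_file is not None:
            out_file.close()

    return records_to_frame(records)


def records_to_frame(records: Iterable[SimulationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=RECORD_COLUMNS)
    return df


@dataclass(frozen=True)
class PowerModel:
    """A fitted logistic power surface: P(significant) = logit^{-1}(Xb)."""

    predictors: tuple[str, ...]
    params: "pd.Series" = field(repr=False)
    bse: "pd.Series" = field(repr=False)
    converged: bool = True
    penalized: bool = False

    def summary_frame(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame({"coef": self.params, "se": self.bse, "z": z})


def _design_matrix(records: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for name in predictors:
        if name == "sqrt_N":
            cols[name] = np.sqrt(records["N"].to_numpy(dtype=float))
        elif name in ("true_necessity", "true_sufficiency"):
            cols[name] = records[name].to_numpy(dtype=float)
        else:
            raise ValidationError(
                f"unknown predictor {name!r}; choose from {PREDICTOR_NAMES}"
            )
    X = pd.DataFrame(cols, index=records.index)
    return sm.add_constant(X, has_constant="add")


def fit_power_model(
    records: pd.DataFrame,
    predictors: Sequence[str] = ("true_necessity", "sqrt_N"),
) -> PowerModel:
    """Maximum-likelihood logistic fit of ``significant ~ predictors``.

    ``predictors`` is any subset of ``true_necessity``, ``true_sufficiency``
    and ``sqrt_N`` (square root of total sample size N = 9 * n_per_x); an
    empty tuple fits the intercept-only model.  On (quasi-)complete
    separation a SeparationWarning is issued and a lightly L2-penalized fit
    is returned instead.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 records to fit a power model")
    y = records["significant"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValidationError(
            "all records share one outcome class; the logistic fit is "
            "unidentified (complete separation)"
        )
    X = _design_matrix(records, predictors)
    model = sm.Logit(y, X)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(disp=0, maxiter=200)
            bad = not np.isfinite(res.params).all() or not np.isfinite(res.bse).all()
        except Exception:
            res, bad = None, True
    separated = bad or any("separation" in str(w.message).lower() for w in caught)
    if separated:
        warnings.warn(
            "perfect separation detected; falling back to an L2-penalized fit",
            SeparationWarning,
            stacklevel=2,
        )
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        res = glm.fit_regularized(alpha=1e-3, L1_wt=0.0)
        params = pd.Series(np.asarray(res.params), index=X.columns)
        bse = pd.Series(np.full(len(params), np.nan), index=X.columns)
        return PowerModel(tuple(predictors), params, bse, penalized=True)
    return PowerModel(
        tuple(predictors),
        pd.Series(res.params, index=X.columns),
        pd.Series(res.bse, index=X.columns),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def predict_power(model: PowerModel, covariates: Mapping[str, float]) -> float:
    """Predicted probability of a significant result at given covariates.

    The fitted log-odds are transformed through the inverse logit.
    Covariates must cover every predictor in the model; ``N`` may be given
    instead of ``sqrt_N``.
    """
    eta = float(model.params["const"])
    for name in model.predictors:
        if name in covariates:
            value = float(covariates[name])
        elif name == "sqrt_N" and "N" in covariates:
            value = float(np.sqrt(covariates["N"]))
        else:
            raise ValidationError(f"missing covariate {name!r}")
        eta += float(model.params[name]) * value
    return float(1.0 / (1.0 + np.exp(-eta)))


def summarize_rejection_rates(
    records: pd.DataFrame,
    group_by: str | None = None,
    bins: int | Sequence[float] | None = None,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Rejection rate per group with Wilson confidence intervals.

    ``group_by`` names a record column; continuous columns can be binned
    into quantile groups by passing ``bins`` (an integer count, e.g. 3 for
    terciles, or explicit edges).  With no grouping, returns the pooled
    rate.  Empty groups are dropped with a log notice.
    """
    if records.empty:
        raise ValidationError("no records to summarize")
    df = records.copy()
    if group_by is None:
        df["_group"] = "all"
    elif bins is not None:
        if isinstance(bins, int):
            df["_group"] = pd.qcut(df[group_by], q=bins, duplicates="drop")
        else:
            df["_group"] = pd.cut(df[group_by], bins=list(bins))
        logger.info("binned %s with edges %s", group_by,
                    sorted(df["_group"].cat.categories.astype(str)))
    else:
        df["_group"] = df[group_by]

    rows = []
    for group, sub in df.groupby("_group", observed=True, sort=True):
        if sub.empty:
            logger.info("group %s is empty; omitted", group)
            continue
        k = int(sub["significant"].sum())
        n = len(sub)
        lo, hi = proportion_confint(k, n, alpha=1 - conf_level, method="wilson")
        rows.append(
            {"group": group, "n": n, "rejections": k,
             "rejection_rate": k / n, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)
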