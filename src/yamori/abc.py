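"""Approximate Bayesian computation for divergence scenarios.

Prior-predictive simulation tables (parameter draws + F_ST / Phi_ST summary
vectors under the structured coalescent), rejection-sampling posteriors, and
model choice between competing scenarios — by accepted-share ("rejection")
or by multinomial logistic regression of model labels on summary statistics
within the jointly accepted set ("mnlogistic"), evaluated at the observed
vector.

Distances are Euclidean on statistics standardized by their median absolute
deviation across the table, the convention of rejection-ABC practice: robust
to the heavy-tailed statistic distributions a diffuse prior produces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels
from .coalescent import SampleConfig, _encode
from .data import SummaryVector
from .models import DemographicModel
from .sumstats import summary_vector_from_counts

logger = logging.getLogger(__name__)

__all__ = [
    "ParamSpec",
    "PriorSpec",
    "SimulationTable",
    "ABCPosterior",
    "ModelChoiceResult",
    "sample_prior",
    "instantiate_model",
    "build_sim_table",
    "abc_reject",
    "model_choice",
    "posterior_quantiles",
]


@dataclass(frozen=True)
class ParamSpec:
    """One scalar parameter: ``ne:<pop>`` (diploid size), ``t:<derived>``
    (split time, generations) or ``mig`` (shared symmetric migration rate)."""

    name: str
    dist: str  # "uniform" | "loguniform"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError("bounds must be finite")
        if self.low > self.high:
            raise ValueError(f"{self.name}: lower bound must be <= upper bound")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError(f"{self.name}: log-uniform needs positive bounds")

    def sample(self, rng: np.random.Generator, size=None):
        if self.low == self.high:  # degenerate (point-mass) prior
            return np.full(size if size is not None else (), self.low)
        if self.dist == "uniform":
            return rng.uniform(self.low, self.high, size)
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size))


@dataclass(frozen=True)
class PriorSpec:
    """Noninformative prior over a scenario's free parameters.

    With ``ordered`` (the default) split times respect the topology: the root
    split is drawn from its own bounds and every descendant split uniformly
    below its parent's drawn time (hierarchical sampling, never rejection, so
    cost is bounded).
    """

    params: tuple[ParamSpec, ...]
    ordered: bool = True

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in prior")

    def get(self, name: str) -> ParamSpec:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    @classmethod
    def default(
        cls,
        model: DemographicModel,
        ne_bounds: tuple[float, float] = (1e3, 1e5),
        root_time_bounds: tuple[float, float] = (100.0, 20_000.0),
        child_time_low: float = 10.0,
        migration_bounds: tuple[float, float] = (1e-8, 1e-2),
    ) -> "PriorSpec":
        """Defaults: log-uniform Ne per population, uniform root split time
        with hierarchical child sampling, log-uniform shared migration rate
        when the template has migration.

        F_ST / Phi_ST are invariant to a joint rescaling of all sizes and
        times, so the absolute time scale of an ABC posterior is set by the
        Ne prior. The default Ne bounds are therefore centered (in log) on
        the 10^4-diploid scale of the study system; widening them downward
        would not add information, it would only shift every inferred age.
        """
        params = [
            ParamSpec(f"ne:{p.name}", "loguniform", *ne_bounds) for p in model.populations
        ]
        root_derived = _root_split(model).derived
        for s in model.splits:
            if s.derived == root_derived:
                params.append(ParamSpec(f"t:{s.derived}", "uniform", *root_time_bounds))
            else:
                params.append(
                    ParamSpec(f"t:{s.derived}", "uniform", child_time_low, root_time_bounds[1])
                )
        if model.migrations:
            params.append(ParamSpec("mig", "loguniform", *migration_bounds))
        return cls(tuple(params))


def _root_split(model: DemographicModel):
    """The oldest split: the one whose ancestral population is the root."""
    root = model.root
    cands = [s for s in model.splits if s.ancestral == root]
    if len(cands) != 1:
        # several children of the root: the oldest split is the root split
        cands = sorted(model.splits, key=lambda s: -s.time_generations)[:1]
    return cands[0]


def _split_order_topdown(model: DemographicModel) -> list:
    """Splits ordered root-ward first so each parent is drawn before its
    children."""
    by_derived = {s.derived: s for s in model.splits}
    root = model.root

    def depth(s):
        d, cur = 0, s.ancestral
        while cur != root:
            cur = by_derived[cur].ancestral
            d += 1
        return d

    return sorted(model.splits, key=depth)


def sample_prior(
    prior: PriorSpec, model_template: DemographicModel, n: int, seed: int = 0
) -> pd.DataFrame:
    """Draw ``n`` parameter vectors. With ordering on, each split time is
    uniform on [low, parent_time), so every draw satisfies the topology's
    child-younger-than-parent constraint by construction."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for p in prior.params:
        if not p.name.startswith("t:"):
            cols[p.name] = p.sample(rng, n)
    if not prior.ordered:
        for p in prior.params:
            if p.name.startswith("t:"):
                cols[p.name] = p.sample(rng, n)
        return pd.DataFrame(cols)
    by_derived = {s.derived: s for s in model_template.splits}
    root_derived = _root_split(model_template).derived
    for s in _split_order_topdown(model_template):
        spec = prior.get(f"t:{s.derived}")
        if s.derived == root_derived:
            cols[spec.name] = spec.sample(rng, n)
        else:
            parent_t = cols[f"t:{by_derived[s.ancestral].derived}"] if s.ancestral in by_derived else None
            if parent_t is None:  # ancestor is the root population: bounded by root split
                parent_t = cols[f"t:{root_derived}"]
            high = np.minimum(spec.high, parent_t)
            degenerate = spec.low == spec.high
            if np.any(spec.low > high) or (degenerate and np.any(parent_t <= spec.low)):
                raise ValueError(
                    f"infeasible prior: lower bound {spec.low} of {spec.name} meets "
                    "its parent's drawn time"
                )
            cols[spec.name] = rng.uniform(spec.low, high)
    order = [p.name for p in prior.params]
    return pd.DataFrame({k: cols[k] for k in order})


def instantiate_model(model_template: DemographicModel, row: pd.Series) -> DemographicModel:
    """Concrete model from one prior draw."""
    ne = {k[3:]: float(v) for k, v in row.items() if k.startswith("ne:")}
    times = {k[2:]: float(v) for k, v in row.items() if k.startswith("t:")}
    model = model_template.with_ne(ne).with_split_times(times)
    if "mig" in row and model.migrations:
        migs = tuple(replace(m, rate_per_generation=float(row["mig"])) for m in model.migrations)
        model = replace(model, migrations=migs)
    return model


@dataclass
class SimulationTable:
    """Prior draws and their simulated summary statistics for one scenario."""

    model_label: str
    params: pd.DataFrame
    stats: pd.DataFrame
    population_order: list[str]
    fst_estimator: str
    master_seed: int
    n_snps: int

    def __post_init__(self) -> None:
        if len(self.params) != len(self.stats):
            raise ValueError("params/stats row mismatch")

    @property
    def n_rows(self) -> int:
        return len(self.params)

    @property
    def ok_rows(self) -> np.ndarray:
        return np.isfinite(self.stats.to_numpy()).all(axis=1)

    def save(self, prefix) -> None:
        """Persist as ``<prefix>.params.tsv``, ``<prefix>.stats.tsv`` and a
        JSON sidecar with the label, seed ledger and statistic definitions."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        self.params.to_csv(f"{prefix}.params.tsv", sep="\t", index=False)
        self.stats.to_csv(f"{prefix}.stats.tsv", sep="\t", index=False)
        meta = {
            "model_label": self.model_label,
            "population_order": self.population_order,
            "fst_estimator": self.fst_estimator,
            "master_seed": self.master_seed,
            "n_snps": self.n_snps,
            "stat_labels": list(self.stats.columns),
        }
        Path(f"{prefix}.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, prefix) -> "SimulationTable":
        import json
        from pathlib import Path

        meta = json.loads(Path(f"{prefix}.json").read_text())
        return cls(
            model_label=meta["model_label"],
            params=pd.read_csv(f"{prefix}.params.tsv", sep="\t"),
            stats=pd.read_csv(f"{prefix}.stats.tsv", sep="\t"),
            population_order=meta["population_order"],
            fst_estimator=meta["fst_estimator"],
            master_seed=meta["master_seed"],
            n_snps=meta["n_snps"],
        )

    def compatible_with(self, observed: SummaryVector) -> bool:
        return (
            list(self.stats.columns) == observed.labels
            and self.population_order == observed.population_order
            and self.fst_estimator == observed.fst_estimator
        )


class _FastScenarioEncoder:
    """Re-encode a scenario template for the kernel without rebuilding model
    objects per draw (the ABC hot loop)."""

    def __init__(self, template: DemographicModel, samples: SampleConfig):
        if template.size_changes:
            raise ValueError("ABC scenario templates must not carry size changes")
        self.template = template
        base = _encode(template, samples)
        self.counts = base[0]
        self.pop_names = list(template.pop_names)
        self.split_derived = np.array(
            [template.pop_index(s.derived) for s in template.splits], dtype=np.int32
        )
        self.split_anc = np.array(
            [template.pop_index(s.ancestral) for s in template.splits], dtype=np.int32
        )
        self.split_names = [s.derived for s in template.splits]
        self.mig_pairs = [
            (template.pop_index(m.source), template.pop_index(m.dest))
            for m in template.migrations
        ]
        self.n_pops = len(template.populations)

    def kernel_args(self, row: pd.Series):
        ne0 = np.array(
            [float(row[f"ne:{name}"]) for name in self.pop_names], dtype=np.float64
        )
        times = np.array(
            [float(row[f"t:{d}"]) for d in self.split_names], dtype=np.float64
        )
        order = np.argsort(times, kind="stable")
        ev_time = times[order]
        ev_kind = np.full(len(order), _kernels.EV_SPLIT, dtype=np.int8)
        ev_a = self.split_derived[order]
        ev_b = self.split_anc[order]
        ev_ne = np.zeros(len(order), dtype=np.float64)
        mig = np.zeros((self.n_pops, self.n_pops), dtype=np.float64)
        use_mig = False
        if self.mig_pairs and "mig" in row:
            rate = float(row["mig"])
            if rate > 0:
                for i, j in self.mig_pairs:
                    mig[i, j] += rate
                use_mig = True
        return self.counts, ne0, ev_time, ev_kind, ev_a, ev_b, ev_ne, mig, use_mig


def build_sim_table(
    model_template: DemographicModel,
    prior: PriorSpec,
    n_sims: int,
    samples: SampleConfig | None = None,
    n_snps: int = 200,
    seed: int = 0,
    model_label: str | None = None,
    population_order: list[str] | None = None,
) -> SimulationTable:
    """Prior-predictive table: for each draw, simulate ``n_snps`` SNPs under
    the instantiated scenario and record the summary vector. Deterministic
    given ``seed``; each row's simulation seed derives from (seed, row), so
    tables are resumable chunk by chunk."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if samples is None:
        samples = SampleConfig.from_model(model_template)
    draws = sample_prior(prior, model_template, n_sims, seed=seed)
    enc = _FastScenarioEncoder(model_template, samples)
    pop_order = population_order or [
        n for n, c in zip(enc.pop_names, enc.counts) if c > 0
    ]
    keep = enc.counts > 0
    sizes = enc.counts[keep].astype(np.int64)
    stats_rows = np.empty((n_sims, len(pop_order) * (len(pop_order) - 1)), dtype=float)
    labels = None
    row_seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31 - 1)
    for i in range(n_sims):
        args = enc.kernel_args(draws.iloc[i])
        cts = _kernels.sim_snp_pop_counts(int(row_seeds[i]), *args, n_snps)
        if cts.shape[0] == 0:
            logger.warning("row %d: simulation failed (stranded lineages); flagged", i)
            stats_rows[i] = np.nan
            continue
        d = cts[:, keep]
        m = np.broadcast_to(sizes, d.shape)
        sv = summary_vector_from_counts(d, m, pop_order)
        stats_rows[i] = sv.values
        if labels is None:
            labels = sv.labels
    stats = pd.DataFrame(stats_rows, columns=labels)
    return SimulationTable(
        model_label=model_label or "model",
        params=draws,
        stats=stats,
        population_order=pop_order,
        fst_estimator="hudson",
        master_seed=seed,
        n_snps=n_snps,
    )


@dataclass
class ABCPosterior:
    """Accepted draws of rejection ABC with their distances."""

    accepted: pd.DataFrame
    distances: np.ndarray
    tolerance: float
    n_table: int
    quantiles: pd.DataFrame

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


def _mad_scale(X: np.ndarray) -> np.ndarray:
    med = np.nanmedian(X, axis=0)
    return np.nanmedian(np.abs(X - med), axis=0)


def _standardized_distances(
    obs: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance after MAD standardization; zero-MAD columns are
    excluded (a constant statistic carries no information) with a warning."""
    mad = _mad_scale(X)
    use = mad > 0
    if not use.all():
        logger.warning(
            "excluding %d zero-variance statistic(s) from the ABC distance",
            int((~use).sum()),
        )
    if not use.any():
        raise ValueError("all summary statistics are constant across the table")
    Z = (X[:, use] - obs[use]) / mad[use]
    d = np.sqrt(np.nansum(Z**2, axis=1))
    d[~np.isfinite(X).all(axis=1)] = np.inf
    return d, use


def abc_reject(
    observed: SummaryVector, table: SimulationTable, tolerance: float
) -> ABCPosterior:
    """Rejection ABC: accept the ``ceil(tolerance * n)`` draws whose
    MAD-standardized summary vectors lie closest to the observed one (ties
    broken by row index)."""
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must lie in (0, 1]")
    if not table.compatible_with(observed):
        raise ValueError("observed vector and table use different statistic definitions")
    X = table.stats.to_numpy()
    d, _ = _standardized_distances(observed.values, X)
    n_acc = math.ceil(tolerance * table.n_rows)
    idx = np.argsort(d, kind="stable")[:n_acc]
    accepted = table.params.iloc[idx].reset_index(drop=True)
    quant = posterior_quantiles_frame(accepted, (0.025, 0.5, 0.975))
    return ABCPosterior(
        accepted=accepted,
        distances=d[idx],
        tolerance=tolerance,
        n_table=table.n_rows,
        quantiles=quant,
    )


def posterior_quantiles_frame(accepted: pd.DataFrame, probs) -> pd.DataFrame:
    if len(accepted) == 0:
        raise ValueError("empty posterior")
    probs = list(probs)
    q = np.quantile(accepted.to_numpy(), probs, axis=0)  # type-7 linear interpolation
    return pd.DataFrame(q, index=[f"q{p}" for p in probs], columns=accepted.columns)


def posterior_quantiles(posterior: ABCPosterior, probs) -> pd.DataFrame:
    """Empirical per-parameter quantiles of the accepted draws."""
    return posterior_quantiles_frame(posterior.accepted, probs)


@dataclass
class ModelChoiceResult:
    """Posterior model probabilities with diagnostics."""

    probabilities: dict[str, float]
    method: str
    accepted_counts: dict[str, int]
    n_accepted: int

    def __post_init__(self) -> None:
        tot = sum(self.probabilities.values())
        if not np.isclose(tot, 1.0, atol=1e-8):
            raise ValueError("model probabilities must sum to 1")

    @property
    def best_model(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)


def model_choice(
    observed: SummaryVector,
    tables: list[SimulationTable],
    tolerance: float,
    method: str = "mnlogistic",
) -> ModelChoiceResult:
    """Posterior probability of each scenario.

    ``rejection``: per-model share of the jointly accepted set.
    ``mnlogistic``: multinomial logistic regression of the model label on the
    MAD-standardized statistics within the jointly accepted set, evaluated at
    the observed vector (falls back to rejection with a warning when the
    accepted set contains a single model).
    """
    if method not in ("rejection", "mnlogistic"):
        raise ValueError(f"unknown method {method!r}")
    if len(tables) < 2:
        raise ValueError("model choice needs at least two tables")
    labels0 = list(tables[0].stats.columns)
    for t in tables:
        if not t.compatible_with(observed) or list(t.stats.columns) != labels0:
            raise ValueError("tables/observed use different statistic definitions")
    names = [t.model_label for t in tables]
    if len(set(names)) != len(names):
        raise ValueError("model labels must be unique")
    X = np.vstack([t.stats.to_numpy() for t in tables])
    y = np.concatenate([np.full(t.n_rows, i) for i, t in enumerate(tables)])
    d, use = _standardized_distances(observed.values, X)
    n_acc = math.ceil(tolerance * len(d))
    idx = np.argsort(d, kind="stable")[:n_acc]
    acc_y = y[idx]
    counts = {nm: int((acc_y == i).sum()) for i, nm in enumerate(names)}
    shares = {nm: counts[nm] / n_acc for nm in names}
    if method == "rejection" or len(np.unique(acc_y)) < 2:
        if method == "mnlogistic":
            logger.warning(
                "accepted set contains a single model; mnlogistic falls back to rejection"
            )
        if len(np.unique(acc_y)) < 2:
            logger.warning("degenerate accepted set: only %s present", names[int(acc_y[0])])
        return ModelChoiceResult(shares, "rejection", counts, n_acc)
    from sklearn.linear_model import LogisticRegression

    mad = _mad_scale(X)
    med = np.nanmedian(X, axis=0)
    Z = (X[idx][:, use] - med[use]) / mad[use]
    z_obs = ((observed.values - med) / np.where(mad > 0, mad, 1.0))[use]
    clf = LogisticRegression(C=1e6, max_iter=2000)  # tiny ridge stabilizes separable sets
    clf.fit(Z, acc_y)
    proba = clf.predict_proba(z_obs.reshape(1, -1))[0]
    full = np.full(len(names), 1e-6)
    for cls, p in zip(clf.classes_, proba):
        full[int(cls)] = min(max(p, 1e-6), 1 - 1e-6)
    full /= full.sum()
    probs = {nm: float(p) for nm, p in zip(names, full)}
    return ModelChoiceResult(probs, "mnlogistic", counts, n_acc)
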