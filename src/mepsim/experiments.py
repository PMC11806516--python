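"""Orchestration of the four simulation studies.

Each study draws fresh training and testing samples per replication,
prepares predictor matrices, fits the requested learners and records
long-form metric rows (scenario, replication, n, k, preparation, learner,
split, metric, value):

* :func:`run_sim1` — ratio outcome with Box-Cox-scale replicate error;
  grid over replicate days at fixed n, all three preparations, both
  learner families (overfitting/transformation study).
* :func:`run_sim2` — same data model, higher skew (Box-Cox exponent 0.5);
  the total measurement budget n*k is held fixed while days vary
  (sample-size versus replicate-count trade-off).
* :func:`run_sim3` — strongly nonlinear continuous outcome with classical
  additive error; error-free and error-prone arms, with and without
  appended log-transformed averaged predictors.
* :func:`run_sim4` — binary outcome with threshold nonlinearities; logistic
  regression and two network training regimes, raw versus log-transformed
  third component, against a constant-model baseline.

Every run is reproducible bit-for-bit from (plan, seed): all randomness
flows from the plan's root seed through named SeedSequence substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .models import GLM, MLPConfig, MLPNetwork, evaluate
from .synthetic_data import feature_matrix, make_scenario, simulate_dataset
from .transforms import ReplicatePreparer, PreparedDesign

RESULT_COLUMNS = [
    "scenario", "replication", "n", "k", "preparation", "learner",
    "split", "metric", "value",
]

__all__ = [
    "ExperimentPlan",
    "RESULT_COLUMNS",
    "default_plan",
    "run_experiment",
    "run_sim1",
    "run_sim2",
    "run_sim3",
    "run_sim4",
    "aggregate",
]


@dataclass
class ExperimentPlan:
    """Declarative description of one simulation study run.

    ``total_measurements`` switches the fixed-budget mode used by the
    trade-off study: the sample size for ``days`` replicates is
    ``total_measurements // days`` (an error if not divisible).
    ``mlp`` holds overrides of the :class:`~mepsim.models.MLPConfig`
    defaults (e.g. smaller ``max_epochs`` for desk-scale runs).
    """

    scenario: str = "sim1"
    n_train: int | None = None
    n_test: int | None = None
    days_grid: tuple = ()
    total_measurements: int | None = None
    preparations: tuple = ("average", "concatenate", "transformed_average")
    learners: tuple = ("linear", "mlp")
    replications: int = 1
    seed: int = 0
    mlp: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in ("sim1", "sim2", "sim3a", "sim3b", "sim4"):
            raise InvalidSpecError(f"unknown scenario {self.scenario!r}")
        self.days_grid = tuple(int(d) for d in self.days_grid)
        if any(d < 1 for d in self.days_grid):
            raise InvalidSpecError("days_grid entries must be positive")
        if self.replications < 0:
            raise InvalidSpecError("replications must be nonnegative")
        self.preparations = tuple(self.preparations)
        self.learners = tuple(self.learners)

    def to_dict(self):
        return asdict(self)


_SCALED_DEFAULTS = {
    # desk-scale problem sizes: small enough for a single CPU, large enough
    # for the qualitative patterns to be resolvable across replications
    "sim1": dict(n_train=2000, n_test=2000, days_grid=(2, 10), replications=3,
                 mlp=dict(max_epochs=600)),
    "sim2": dict(total_measurements=24000, days_grid=(2, 4, 10), replications=3,
                 preparations=("transformed_average",), learners=("mlp",),
                 mlp=dict(max_epochs=600)),
    "sim3a": dict(n_train=5000, n_test=5000, replications=10,
                  mlp=dict(max_epochs=500)),
    "sim3b": dict(n_train=5000, n_test=5000, replications=10,
                  mlp=dict(max_epochs=500)),
    "sim4": dict(n_train=2500, n_test=2500, replications=10,
                 mlp=dict(max_epochs=500)),
}

_FULL_DEFAULTS = {
    "sim1": dict(n_train=12000, n_test=12000, days_grid=(2, 4, 6, 8, 10),
                 replications=10),
    "sim2": dict(total_measurements=60000, days_grid=(2, 4, 6, 8, 10),
                 replications=10),
    "sim3a": dict(n_train=40000, n_test=40000, replications=100),
    "sim3b": dict(n_train=40000, n_test=40000, replications=100),
    "sim4": dict(n_train=10000, n_test=10000, replications=100),
}


def default_plan(scenario, scaled=True, seed=0, **overrides):
    """Catalogued plan for a scenario, at desk scale or published scale."""
    base = dict((_SCALED_DEFAULTS if scaled else _FULL_DEFAULTS)[scenario])
    base.update(overrides)
    return ExperimentPlan(scenario=scenario, seed=seed, **base)


def _model_seed(ss):
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _make_learner(name, plan, output_link="identity", seed=0):
    if name in ("linear", "logistic"):
        return GLM(link="identity" if name == "linear" else "expit")
    cfg = asdict(MLPConfig())
    cfg.update(plan.mlp)
    cfg.update(output_link=output_link, seed=seed)
    if name == "mlp":
        return MLPNetwork(**cfg)
    if name == "mlp_early":  # aggressive regime: small batches, frequent checks
        cfg.update(batch_size=250, early_stop_every=10)
        return MLPNetwork(**cfg)
    raise InvalidSpecError(f"unknown learner {name!r}")


def _rows_frame(rows):
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _fit_and_record(rows, base, learner_name, model, des_tr, y_tr, des_te, y_te,
                    metric):
    model.fit(des_tr, y_tr)
    for split, des, y in (("train", des_tr, y_tr), ("test", des_te, y_te)):
        value = evaluate(model.predict(des), y, metric=metric)
        rows.append({**base, "learner": learner_name, "split": split,
                     "metric": metric, "value": value})


# ---------------------------------------------------------------------------
# simulation 1: transformations and overfitting


def run_sim1(plan):
    if plan.scenario != "sim1":
        raise InvalidSpecError("run_sim1 requires scenario sim1")
    scenario = make_scenario("sim1")
    days_grid = plan.days_grid or scenario.days_grid
    n_train = plan.n_train or scenario.n_train
    n_test = plan.n_test or scenario.n_test
    k_max = max(days_grid)
    root = np.random.SeedSequence(plan.seed)
    rows = []
    for rep in range(plan.replications):
        s_train, s_test, s_models = root.spawn(3)
        train = simulate_dataset(scenario, n_train, k_max, s_train)
        test = simulate_dataset(scenario, n_test, k_max, s_test)
        for days in days_grid:
            for prep in plan.preparations:
                preparer = ReplicatePreparer(strategy=prep, days_used=days)
                des_tr = preparer.fit_transform(train)
                des_te = preparer.transform(test)
                base = dict(scenario="sim1", replication=rep, n=n_train,
                            k=days, preparation=prep)
                for learner in plan.learners:
                    model = _make_learner(
                        learner, plan, seed=_model_seed(s_models.spawn(1)[0])
                    )
                    _fit_and_record(rows, base, learner, model, des_tr,
                                    train.Y, des_te, test.Y, "mse")
    return _rows_frame(rows)


# ---------------------------------------------------------------------------
# simulation 2: sample size versus replicate count at fixed budget


def run_sim2(plan):
    if plan.scenario != "sim2":
        raise InvalidSpecError("run_sim2 requires scenario sim2")
    if not plan.total_measurements:
        raise InvalidSpecError("sim2 requires total_measurements")
    scenario = make_scenario("sim2")
    days_grid = plan.days_grid or scenario.days_grid
    total = int(plan.total_measurements)
    for days in days_grid:
        if total % days:
            raise InvalidSpecError(
                f"total_measurements={total} not divisible by days={days}"
            )
    root = np.random.SeedSequence(plan.seed)
    rows = []
    for rep in range(plan.replications):
        for days in days_grid:
            n = total // days
            s_train, s_test, s_models = root.spawn(3)
            train = simulate_dataset(scenario, n, days, s_train)
            n_test = plan.n_test or n
            test = simulate_dataset(scenario, n_test, days, s_test)
            for prep in plan.preparations:
                preparer = ReplicatePreparer(strategy=prep, days_used=days)
                des_tr = preparer.fit_transform(train)
                des_te = preparer.transform(test)
                base = dict(scenario="sim2", replication=rep, n=n, k=days,
                            preparation=prep)
                for learner in plan.learners:
                    model = _make_learner(
                        learner, plan, seed=_model_seed(s_models.spawn(1)[0])
                    )
                    _fit_and_record(rows, base, learner, model, des_tr,
                                    train.Y, des_te, test.Y, "mse")
    return _rows_frame(rows)


# ---------------------------------------------------------------------------
# simulation 3: nonlinear outcome, error-free versus error-prone arms


def _sim3_design(dataset, arm, outcome):
    Z = dataset.Z
    zcols = [f"z{m + 1}" for m in range(Z.shape[1])]
    if arm == "true_linear":
        M = np.hstack([dataset.Xtrue, Z])
        cols = ["xtrue1", "xtrue2", *zcols]
    elif arm == "true_oracle":
        # correctly specified mean model: OLS on these columns attains the
        # sigmaY2 floor
        M = feature_matrix(outcome, dataset.Xtrue, Z)
        cols = ["x1", "x2", "x1x2", "logx1", "logx2", "ratio", "z3"]
    elif arm in ("avg_linear", "avg_log"):
        Xbar = dataset.Xstar.mean(axis=2)
        if arm == "avg_linear":
            M = np.hstack([Xbar, Z])
            cols = ["x1_avg", "x2_avg", *zcols]
        else:
            M = np.hstack([Xbar, np.log(Xbar), Z])
            cols = ["x1_avg", "x2_avg", "logx1_avg", "logx2_avg", *zcols]
    else:
        raise InvalidSpecError(f"unknown sim3 arm {arm!r}")
    return PreparedDesign(M=M, columns=cols, strategy=arm, k_used=dataset.k)


_SIM3_ARMS = ("true_linear", "true_oracle", "avg_linear", "avg_log")


def run_sim3(plan):
    if plan.scenario not in ("sim3a", "sim3b"):
        raise InvalidSpecError("run_sim3 requires scenario sim3a or sim3b")
    scenario = make_scenario(plan.scenario)
    n_train = plan.n_train or scenario.n_train
    n_test = plan.n_test or scenario.n_test
    root = np.random.SeedSequence(plan.seed)
    rows = []
    for rep in range(plan.replications):
        s_train, s_test, s_models = root.spawn(3)
        train = simulate_dataset(scenario, n_train, scenario.k, s_train)
        test = simulate_dataset(scenario, n_test, scenario.k, s_test)
        for arm in _SIM3_ARMS:
            des_tr = _sim3_design(train, arm, scenario.outcome)
            des_te = _sim3_design(test, arm, scenario.outcome)
            base = dict(scenario=plan.scenario, replication=rep, n=n_train,
                        k=scenario.k, preparation=arm)
            for learner in plan.learners:
                if learner != "linear" and arm == "true_oracle":
                    continue  # the oracle arm is the specification check
                model = _make_learner(
                    learner, plan, seed=_model_seed(s_models.spawn(1)[0])
                )
                _fit_and_record(rows, base, learner, model, des_tr, train.Y,
                                des_te, test.Y, "mse")
    return _rows_frame(rows)


# ---------------------------------------------------------------------------
# simulation 4: binary prediction


def _sim4_design(dataset, prep):
    Xbar = dataset.Xstar.mean(axis=2)
    if prep == "avg":
        M, cols = Xbar, ["x1_avg", "x2_avg", "x3_avg"]
    elif prep == "avg_log3":
        M = np.column_stack([Xbar[:, 0], Xbar[:, 1], np.log(Xbar[:, 2])])
        cols = ["x1_avg", "x2_avg", "logx3_avg"]
    else:
        raise InvalidSpecError(f"unknown sim4 preparation {prep!r}")
    return PreparedDesign(M=M, columns=cols, strategy=prep, k_used=dataset.k)


_SIM4_LEARNERS = ("logistic", "mlp", "mlp_early")


def run_sim4(plan):
    if plan.scenario != "sim4":
        raise InvalidSpecError("run_sim4 requires scenario sim4")
    scenario = make_scenario("sim4")
    n_train = plan.n_train or scenario.n_train
    n_test = plan.n_test or scenario.n_test
    learners = plan.learners if plan.learners != ("linear", "mlp") else _SIM4_LEARNERS
    root = np.random.SeedSequence(plan.seed)
    rows = []
    for rep in range(plan.replications):
        s_train, s_test, s_models = root.spawn(3)
        train = simulate_dataset(scenario, n_train, scenario.k, s_train)
        test = simulate_dataset(scenario, n_test, scenario.k, s_test)
        # constant-model baseline: majority class of the training data
        majority = float(train.Y.mean() >= 0.5)
        for split, y in (("train", train.Y), ("test", test.Y)):
            rows.append(dict(scenario="sim4", replication=rep, n=n_train,
                             k=scenario.k, preparation="none",
                             learner="constant", split=split,
                             metric="accuracy",
                             value=float(np.mean(y == majority))))
        for prep in ("avg", "avg_log3"):
            des_tr = _sim4_design(train, prep)
            des_te = _sim4_design(test, prep)
            base = dict(scenario="sim4", replication=rep, n=n_train,
                        k=scenario.k, preparation=prep)
            for learner in learners:
                model = _make_learner(
                    learner, plan, output_link="expit",
                    seed=_model_seed(s_models.spawn(1)[0]),
                )
                _fit_and_record(rows, base, learner, model, des_tr, train.Y,
                                des_te, test.Y, "accuracy")
    return _rows_frame(rows)


_RUNNERS = {"sim1": run_sim1, "sim2": run_sim2, "sim3a": run_sim3,
            "sim3b": run_sim3, "sim4": run_sim4}


def run_experiment(plan):
    """Dispatch a plan to its scenario runner."""
    return _RUNNERS[plan.scenario](plan)


def aggregate(results):
    """Mean and standard deviation of each grid cell over replications."""
    if results.empty:
        return results
    keys = ["scenario", "n", "k", "preparation", "learner", "split", "metric"]
    return (
        results.groupby(keys, as_index=False)["value"]
        .agg(mean="mean", sd="std", reps="count")
    )
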