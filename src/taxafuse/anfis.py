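"""Takagi–Sugeno fuzzy rule inference over an augmented abundance matrix.

Sparse, small-effect-size abundance data is converted into a compact integer
"rule matrix": each training sample nominates a fuzzy IF-THEN rule whose
antecedent is, per input variable, the index of the Gaussian membership term
the sample activates most strongly (one-rule-per-sample generation in the
Wang–Mendel style); duplicate antecedents collapse, keeping the candidate of
highest degree. Rule consequents are first-order linear functions fitted by a
hybrid scheme that alternates a global least-squares solve for the consequent
coefficients with a gradient step on the Gaussian premise parameters.

The resulting rows are "effective samples", the columns "effective features",
and the final column — the output variable's term index — the "effective
label". Because the rule matrix is built from per-variable discretisations of
the original columns it retains the intra-feature correlation structure, which
:func:`correlation_preservation` quantifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import AugmentedMatrix, autoscale

__all__ = [
    "FuzzyVariable",
    "Rule",
    "TSModel",
    "InferredMatrix",
    "build_fuzzy_variables",
    "generate_rules",
    "hybrid_learn",
    "predict",
    "extract_inferred_matrix",
    "correlation_preservation",
    "infer_rule_matrix",
]

# adjacent Gaussians cross at membership 0.5 when sigma = spacing / (2*sqrt(2 ln 2))
_HALF_CROSS = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class FuzzyVariable:
    """One input (or output) variable with an ordered bank of Gaussian terms."""

    name: str
    means: np.ndarray          # strictly increasing term centres
    sigmas: np.ndarray         # positive term widths
    domain: tuple[float, float]

    @property
    def n_terms(self) -> int:
        return len(self.means)

    def memberships(self, x: np.ndarray) -> np.ndarray:
        """Gaussian membership of each value of ``x`` in each term, shape (n, T)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.means[None, :]) / self.sigmas[None, :]
        return np.exp(-0.5 * z**2)


@dataclass
class Rule:
    antecedent: tuple[int, ...]          # 1-based term index per input variable
    output_term: int                     # 1-based term index of the output variable
    consequent: np.ndarray               # (n_inputs + 1,): intercept + slopes
    degree: float                        # product of generating-sample memberships


@dataclass
class TSModel:
    """A trained Takagi–Sugeno system: variable banks plus IF-THEN rules."""

    input_variables: list[FuzzyVariable]
    output_variable: FuzzyVariable
    rules: list[Rule]
    num_labels: int
    rmse_trajectory: list[float] = field(default_factory=list)
    sse_before_pass: list[float] = field(default_factory=list)
    sse_after_pass: list[float] = field(default_factory=list)
    iterations_run: int = 0

    @property
    def n_inputs(self) -> int:
        return len(self.input_variables)

    @property
    def n_rules(self) -> int:
        return len(self.rules)


@dataclass
class InferredMatrix:
    """Integer rule matrix: effective samples × (effective features + label)."""

    values: np.ndarray                   # int matrix, entries in 1..num_labels
    feature_names: list[str]             # names of the effective features
    num_labels: int
    scaled_values: np.ndarray = field(default=None)  # auto-scaled copy

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.scaled_values is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant columns are expected
                self.scaled_values = autoscale(self.values.astype(float))

    @property
    def n_rules(self) -> int:
        return self.values.shape[0]

    @property
    def effective_label(self) -> np.ndarray:
        """Integer effective-label column (last column of the rule matrix)."""
        return self.values[:, -1]

    @property
    def scaled_features(self) -> np.ndarray:
        return self.scaled_values[:, :-1]


def build_fuzzy_variables(
    matrix: AugmentedMatrix | np.ndarray,
    num_labels: int = 7,
    names: list[str] | None = None,
) -> list[FuzzyVariable]:
    """Place ``num_labels`` Gaussian terms per column, equally spaced over its
    observed range, with widths chosen so adjacent terms cross at membership
    0.5. Constant columns receive a single degenerate term.
    """
    if num_labels < 2:
        raise ValueError(f"num_labels must be >= 2, got {num_labels}")
    values = matrix.values if isinstance(matrix, AugmentedMatrix) else np.asarray(matrix, float)
    if names is None:
        if isinstance(matrix, AugmentedMatrix):
            names = matrix.feature_names + ["label"]
        else:
            names = [f"x{j}" for j in range(values.shape[1])]
    out: list[FuzzyVariable] = []
    for j, name in enumerate(names):
        lo, hi = float(values[:, j].min()), float(values[:, j].max())
        if hi - lo < 1e-15:
            out.append(FuzzyVariable(name, np.array([lo]), np.array([1.0]), (lo, hi)))
            continue
        means = np.linspace(lo, hi, num_labels)
        spacing = (hi - lo) / (num_labels - 1)
        sigma = spacing * _HALF_CROSS
        out.append(FuzzyVariable(name, means, np.full(num_labels, sigma), (lo, hi)))
    return out


def _argmax_terms(var: FuzzyVariable, column: np.ndarray) -> np.ndarray:
    """1-based index of the most-activated term per value; ties take the lower index."""
    m = var.memberships(column)
    return np.argmax(m, axis=1) + 1  # np.argmax returns the first (lowest) maximum


def generate_rules(
    matrix: AugmentedMatrix | np.ndarray,
    variables: list[FuzzyVariable],
) -> list[Rule]:
    """One candidate rule per training sample; duplicate antecedents collapse,
    keeping the candidate of highest degree."""
    values = matrix.values if isinstance(matrix, AugmentedMatrix) else np.asarray(matrix, float)
    if values.size == 0:
        raise ValueError("cannot generate rules from an empty matrix")
    if len(variables) != values.shape[1]:
        raise ValueError("one fuzzy variable required per column (inputs + output)")

    n, _ = values.shape
    n_inputs = len(variables) - 1
    term_idx = np.column_stack([_argmax_terms(v, values[:, j]) for j, v in enumerate(variables)])
    # degree = product of memberships of the generating sample over all variables
    degrees = np.ones(n)
    for j, v in enumerate(variables):
        m = v.memberships(values[:, j])
        degrees *= m[np.arange(n), term_idx[:, j] - 1]

    best: dict[tuple[int, ...], tuple[float, int]] = {}
    for i in range(n):
        ant = tuple(int(t) for t in term_idx[i, :n_inputs])
        if ant not in best or degrees[i] > best[ant][0]:
            best[ant] = (float(degrees[i]), i)

    rules = []
    for ant, (deg, i) in best.items():
        rules.append(
            Rule(
                antecedent=ant,
                output_term=int(term_idx[i, -1]),
                consequent=np.zeros(n_inputs + 1),
                degree=deg,
            )
        )
    return rules


def _firing_strengths(model: TSModel, X: np.ndarray) -> np.ndarray:
    """Rule firing strengths w_r(x) for each row of X, shape (n, R)."""
    n = X.shape[0]
    memberships = [v.memberships(X[:, j]) for j, v in enumerate(model.input_variables)]
    W = np.ones((n, model.n_rules))
    for r, rule in enumerate(model.rules):
        for j, t in enumerate(rule.antecedent):
            W[:, r] *= memberships[j][:, t - 1]
    return W


def _lse_consequents(model: TSModel, X: np.ndarray, y: np.ndarray) -> None:
    """Global least-squares solve for all consequent coefficients."""
    n, p = X.shape
    R = model.n_rules
    W = _firing_strengths(model, X)
    S = W.sum(axis=1, keepdims=True)
    S[S < 1e-300] = 1.0
    Wn = W / S
    ones = np.column_stack([np.ones(n), X])          # (n, p+1)
    # design: column block per rule, weighted by its normalised firing strength
    Phi = (Wn[:, :, None] * ones[:, None, :]).reshape(n, R * (p + 1))
    theta, _, rank, _ = np.linalg.lstsq(Phi, y, rcond=None)
    if rank < min(Phi.shape):
        warnings.warn(
            "singular consequent system; minimum-norm (ridge-limit) solution used",
            stacklevel=2,
        )
    theta = theta.reshape(R, p + 1)
    for r, rule in enumerate(model.rules):
        rule.consequent = theta[r]


def _batch_predict(model: TSModel, X: np.ndarray) -> np.ndarray:
    W = _firing_strengths(model, X)
    S = W.sum(axis=1)
    ones = np.column_stack([np.ones(X.shape[0]), X])
    F = ones @ np.stack([r.consequent for r in model.rules]).T   # (n, R)
    safe = S > 1e-300
    out = np.empty(X.shape[0])
    out[safe] = (W[safe] * F[safe]).sum(axis=1) / S[safe]
    if not np.all(safe):
        # fall back to the nearest rule by antecedent-mean distance
        centres = _rule_centres(model)
        for i in np.where(~safe)[0]:
            r = int(np.argmin(((centres - X[i]) ** 2).sum(axis=1)))
            out[i] = F[i, r]
    return out


def _rule_centres(model: TSModel) -> np.ndarray:
    centres = np.zeros((model.n_rules, model.n_inputs))
    for r, rule in enumerate(model.rules):
        for j, t in enumerate(rule.antecedent):
            centres[r, j] = model.input_variables[j].means[t - 1]
    return centres


def _premise_gradient_step(model: TSModel, X: np.ndarray, y: np.ndarray, step_size: float) -> None:
    """One gradient-descent step on the Gaussian means and sigmas."""
    n, p = X.shape
    W = _firing_strengths(model, X)
    S = W.sum(axis=1, keepdims=True)
    S[S < 1e-300] = 1.0
    ones = np.column_stack([np.ones(n), X])
    F = ones @ np.stack([r.consequent for r in model.rules]).T
    yhat = (W * F).sum(axis=1) / S[:, 0]
    err = yhat - y
    # G[i, r] = dSSE/dW_ir = 2 e_i (f_ir - yhat_i) / S_i
    G = 2.0 * err[:, None] * (F - yhat[:, None]) / S

    ant = np.array([r.antecedent for r in model.rules])  # (R, p), 1-based
    for j, var in enumerate(model.input_variables):
        if var.n_terms < 2:
            continue
        onehot = np.zeros((model.n_rules, var.n_terms))
        onehot[np.arange(model.n_rules), ant[:, j] - 1] = 1.0
        A = (G * W) @ onehot                       # (n, T): sum over rules using term k
        diff = X[:, j][:, None] - var.means[None, :]
        grad_mean = (A * diff / var.sigmas[None, :] ** 2).sum(axis=0)
        grad_sigma = (A * diff**2 / var.sigmas[None, :] ** 3).sum(axis=0)
        var.means = var.means - step_size * grad_mean / n
        new_sigma = var.sigmas - step_size * grad_sigma / n
        var.sigmas = np.maximum(new_sigma, 1e-6)


def hybrid_learn(
    model: TSModel,
    matrix: AugmentedMatrix | np.ndarray,
    max_iter: int = 10,
    step_size: float = 0.01,
) -> TSModel:
    """Alternate global least squares on the consequents with a premise
    gradient step. The training SSE immediately after each least-squares pass
    never exceeds the SSE immediately before it (the solve is optimal for the
    current premises)."""
    if model.n_rules < 1:
        raise ValueError("model has no rules")
    values = matrix.values if isinstance(matrix, AugmentedMatrix) else np.asarray(matrix, float)
    X, y = values[:, :-1], values[:, -1]
    model.rmse_trajectory = []
    model.sse_before_pass = []
    model.sse_after_pass = []
    for it in range(max_iter):
        pre = _batch_predict(model, X) - y
        model.sse_before_pass.append(float(np.sum(pre**2)))
        _lse_consequents(model, X, y)
        resid = _batch_predict(model, X) - y
        sse = float(np.sum(resid**2))
        model.sse_after_pass.append(sse)
        model.rmse_trajectory.append(float(np.sqrt(sse / len(y))))
        if it < max_iter - 1:
            _premise_gradient_step(model, X, y, step_size)
    model.iterations_run = max_iter
    return model


def predict(model: TSModel, x: np.ndarray) -> float:
    """Weighted-average defuzzified output at a single input point."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ValueError(f"expected input of length {model.n_inputs}, got {x.shape}")
    return float(_batch_predict(model, x[None, :])[0])


def extract_inferred_matrix(model: TSModel, feature_names: list[str] | None = None) -> InferredMatrix:
    """Render the rule base as the integer inferred matrix (term indices), the
    last column being the effective label."""
    if model.n_rules < 1:
        raise ValueError("model has no rules")
    rows = [list(r.antecedent) + [r.output_term] for r in model.rules]
    values = np.asarray(rows, dtype=int)
    if feature_names is None:
        feature_names = [v.name for v in model.input_variables]
    return InferredMatrix(values=values, feature_names=list(feature_names), num_labels=model.num_labels)


def infer_rule_matrix(
    matrix: AugmentedMatrix,
    num_labels: int = 7,
    max_iter: int = 10,
    step_size: float = 0.01,
) -> tuple[TSModel, InferredMatrix]:
    """End-to-end stage 1: fuzzify, generate rules, hybrid-learn, extract."""
    variables = build_fuzzy_variables(matrix, num_labels)
    rules = generate_rules(matrix, variables)
    model = TSModel(
        input_variables=variables[:-1],
        output_variable=variables[-1],
        rules=rules,
        num_labels=num_labels,
    )
    hybrid_learn(model, matrix, max_iter=max_iter, step_size=step_size)
    inferred = extract_inferred_matrix(model, matrix.feature_names)
    return model, inferred


def correlation_preservation(
    before: np.ndarray, after: np.ndarray
) -> tuple[float, np.ndarray]:
    """Max absolute elementwise difference between the Pearson correlation
    matrices of two matrices sharing feature columns.

    Rows need not match (the rule matrix usually has fewer rows than the
    abundance matrix); constant columns contribute zero correlations.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape[1] != after.shape[1]:
        raise ValueError("matrices must share feature columns")
    if before.shape[0] < 3 or after.shape[0] < 3:
        raise ValueError("need at least 3 rows to estimate correlations")

    def _corr(m: np.ndarray) -> np.ndarray:
        sd = m.std(axis=0, ddof=1)
        constant = sd < 1e-15
        if np.any(constant):
            warnings.warn(
                f"{int(constant.sum())} constant column(s): correlations set to 0",
                stacklevel=3,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(m, rowvar=False)
        c = np.atleast_2d(c)
        c[np.isnan(c)] = 0.0
        np.fill_diagonal(c, 1.0)
        return c

    diff = np.abs(_corr(before) - _corr(after))
    np.fill_diagonal(diff, 0.0)
    off = diff[~np.eye(diff.shape[0], dtype=bool)]
    return (float(off.max()) if off.size else 0.0, diff)
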