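import warnings

import numpy as np
import pytest

import taxafuse as tf


@pytest.fixture(autouse=True)
def _quiet():
    """Library warnings (constant columns, ridge fallbacks) are expected in
    many constructions below; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def small_table():
    """3 samples x 2 features with HC/UC labels."""
    return tf.AbundanceTable(
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        sample_ids=["s1", "s2", "s3"],
        feature_names=["fA", "fB"],
        labels=["HC", "UC", "HC"],
    )


@pytest.fixture(scope="session")
def default_fixture_run():
    """One end-to-end run (stages 1-3) on the default synthetic fixture;
    session-scoped because the fuzzy-rule stage is the expensive part."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = tf.FixtureSpec(seed=11)
        table, truth = tf.make_abundance(spec)
        aug = tf.augment(table)
        model, inferred = tf.infer_rule_matrix(aug)
        eps, assignment, clustered = tf.select_epsilon(inferred)
        scores = tf.score_pipeline(clustered, inferred.scaled_values[:, -1], seed=11)
    return {
        "spec": spec,
        "table": table,
        "truth": truth,
        "aug": aug,
        "model": model,
        "inferred": inferred,
        "eps": eps,
        "assignment": assignment,
        "clustered": clustered,
        "scores": scores,
    }


def lasso_cd_reference(X, y, lam, w=None, n_iter=20000, tol=1e-12):
    """Independent coordinate-descent solver for
    argmin ||y - X b||^2 + lam * sum_j w_j |b_j| (no intercept).

    Deliberately naive (plain Gauss-Seidel soft-thresholding) so it shares no
    code path with the package's solver.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    w = np.ones(p) if w is None else np.asarray(w, float)
    b = np.zeros(p)
    col_sq = (X**2).sum(axis=0)
    r = y.copy()
    for _ in range(n_iter):
        b_old = b.copy()
        for j in range(p):
            if col_sq[j] == 0:
                continue
            r = r + X[:, j] * b[j]
            rho = X[:, j] @ r
            thresh = lam * w[j] / 2.0
            bj = np.sign(rho) * max(abs(rho) - thresh, 0.0) / col_sq[j]
            b[j] = bj
            r = r - X[:, j] * bj
        if np.max(np.abs(b - b_old)) < tol:
            break
    return b
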