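"""Group collinear effective features with DBSCAN at an auto-selected eps.

Feature columns of the auto-scaled rule matrix are clustered; eps rises
through a grid (1 to the largest term index, step 0.5) until the collapsed
design matrix is free of aliased columns — the condition under which a GLM
would report NA coefficients. Each cluster is replaced by its first
principal-component linear combination.
"""

import warnings

import taxafuse as tf

warnings.filterwarnings("ignore")

table, truth = tf.make_abundance(tf.FixtureSpec(seed=7))
aug = tf.augment(table)
_, inferred = tf.infer_rule_matrix(aug)

eps, assignment, clustered = tf.select_epsilon(inferred)
print(f"selected eps = {eps}; clusters found: {assignment.n_clusters}")
print(f"columns: {len(inferred.feature_names)} -> {clustered.n_columns} after collapsing")
for name, members in clustered.provenance.items():
    if len(members) > 1:
        loads = {f: round(c, 3) for f, c in clustered.loadings[name].items()}
        print(f"  {name}: {loads}")
# the loadings are the coefficients of the linear combination replacing a cluster
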