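"""Naive from-first-principles reference implementations of every validation
statistic, written with explicit loops and refits so they share no code path
with the package. Used to cross-check the fast implementations."""

import numpy as np


def ols_beta(X, y):
    """Normal-equation OLS via pseudoinverse (independent of the QR path)."""
    A = np.column_stack([np.ones(len(X)), X])
    return np.linalg.pinv(A) @ y


def ols_predict(beta, X):
    return beta[0] + np.asarray(X) @ beta[1:]


def r2_oracle(y, yhat):
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    return 1.0 - np.sum((y - yhat) ** 2) / np.sum((y - np.mean(y)) ** 2)


def press_loo_refit(X, y):
    """PRESS by literally refitting n times with one point left out."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        beta = ols_beta(X[mask], y[mask])
        press += (y[i] - ols_predict(beta, X[i:i + 1])[0]) ** 2
    return press


def q2_loo_refit(X, y):
    y = np.asarray(y, float)
    return 1.0 - press_loo_refit(X, y) / np.sum((y - y.mean()) ** 2)


def ccc_oracle(y, yhat):
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    n = len(y)
    my, mp = y.mean(), yhat.mean()
    sy2 = sum((v - my) ** 2 for v in y) / n
    sp2 = sum((v - mp) ** 2 for v in yhat) / n
    cov = sum((a - my) * (b - mp) for a, b in zip(y, yhat)) / n
    return 2 * cov / (sy2 + sp2 + (my - mp) ** 2)


def q2f_oracle(y_ex, yhat_ex, y_tr):
    y_ex, yhat_ex, y_tr = map(lambda v: np.asarray(v, float), (y_ex, yhat_ex, y_tr))
    press = sum((a - b) ** 2 for a, b in zip(yhat_ex, y_ex))
    f1 = 1 - press / sum((v - y_tr.mean()) ** 2 for v in y_ex)
    f2 = 1 - press / sum((v - y_ex.mean()) ** 2 for v in y_ex)
    f3 = 1 - (press / len(y_ex)) / (sum((v - y_tr.mean()) ** 2 for v in y_tr) / len(y_tr))
    return f1, f2, f3


def rm2_oracle(y_obs, y_pred):
    """Roy's through-origin metrics by direct formula evaluation."""
    y_obs, y_pred = np.asarray(y_obs, float), np.asarray(y_pred, float)
    r2 = np.corrcoef(y_obs, y_pred)[0, 1] ** 2
    k = sum(a * b for a, b in zip(y_pred, y_obs)) / sum(b * b for b in y_pred)
    kp = sum(a * b for a, b in zip(y_pred, y_obs)) / sum(a * a for a in y_obs)
    r2o = 1 - sum((a - k * b) ** 2 for a, b in zip(y_obs, y_pred)) / sum(
        (a - y_obs.mean()) ** 2 for a in y_obs)
    r2op = 1 - sum((b - kp * a) ** 2 for a, b in zip(y_obs, y_pred)) / sum(
        (b - y_pred.mean()) ** 2 for b in y_pred)
    rm2 = r2 * (1 - np.sqrt(max(r2 - r2o, 0.0)))
    rm2p = r2 * (1 - np.sqrt(max(r2 - r2op, 0.0)))
    return {"k": k, "k_prime": kp, "r2o": r2o, "r2o_prime": r2op,
            "rm2_avg": (rm2 + rm2p) / 2, "rm2_delta": abs(rm2 - rm2p)}


def k_index_oracle(block):
    """Todeschini K by direct eigendecomposition of the correlation matrix."""
    block = np.asarray(block, float)
    m = block.shape[1]
    corr = np.ones((m, m))
    for i in range(m):
        for j in range(m):
            xi = block[:, i] - block[:, i].mean()
            xj = block[:, j] - block[:, j].mean()
            corr[i, j] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
    lam = np.abs(np.linalg.eigvals(corr))
    frac = lam / lam.sum()
    return sum(abs(f - 1.0 / m) for f in frac) / (2 * (m - 1) / m)


def leverage_oracle(X_tr, X_query):
    """Leverage by direct (A'A)^-1 with explicit matrix inversion."""
    A = np.column_stack([np.ones(len(X_tr)), X_tr])
    inv = np.linalg.inv(A.T @ A)
    out = []
    for row in np.asarray(X_query, float):
        a = np.concatenate([[1.0], row])
        out.append(float(a @ inv @ a))
    return np.array(out)


def bfs_distances_oracle(rdmol):
    """All-pairs shortest path bond counts via networkx BFS; -1 unreachable."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(rdmol.GetNumAtoms()))
    for b in rdmol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    n = rdmol.GetNumAtoms()
    out = -np.ones((n, n), dtype=int)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            out[src, dst] = d
    return out
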