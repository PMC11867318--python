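"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately written from first principles (fixed-step
RK4, NIPALS PLS, hand-rolled Pearson chi-square, brute-force nearest
centroid) and shares no code with the implementation paths it checks.
"""

import numpy as np


def rk4_glv(k, alpha, x0, t0, t1, h=1e-3, kill_windows=(), nab_index=0):
    """Fixed-step RK4 for dx_i/dt = x_i (g_i + (alpha x)_i); returns x(t1)."""
    k = np.asarray(k, float)
    alpha = np.asarray(alpha, float)
    x = np.asarray(x0, float).copy()
    n_steps = int(round((t1 - t0) / h))

    def g_at(t):
        g = k.copy()
        for (ws, we, kk) in kill_windows:
            if ws <= t < we:
                g[nab_index] = kk
        return g

    def f(t, y):
        return y * (g_at(t) + alpha @ y)

    t = t0
    for _ in range(n_steps):
        k1 = f(t, x)
        k2 = f(t + h / 2, x + h / 2 * k1)
        k3 = f(t + h / 2, x + h / 2 * k2)
        k4 = f(t + h, x + h * k3)
        x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return x


def logistic_solution(k, a_self, x0, t):
    """Closed-form 1-species logistic with carrying capacity K = k/|a_self|."""
    K = k / abs(a_self)
    if x0 == 0:
        return 0.0
    return K * x0 * np.exp(k * t) / (K + x0 * (np.exp(k * t) - 1.0))


def nearest_centroid_bruteforce(rel, centroid_rows, labels):
    """First label attaining the minimal Euclidean distance (priority order)."""
    best, best_d = None, np.inf
    for lab, c in zip(labels, centroid_rows):
        d = float(((np.asarray(rel) - np.asarray(c)) ** 2).sum())
        if d < best_d - 1e-12:
            best, best_d = lab, d
    return best


def pearson_chi2_2x2(a, b, c, d):
    """Pearson chi-square statistic for [[a, b], [c, d]] without correction."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up recursion."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def nipals_pls2(X, Y, n_components=2, max_iter=500, tol=1e-10):
    """Two-block PLS (PLS2) via the classical NIPALS algorithm.

    X is z-scored and Y centered, as in the implementation under test.
    Returns x_scores T (n, A) and x_loadings P (p, A).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    Y = Y - Y.mean(0)
    T, P = [], []
    Xk, Yk = X.copy(), Y.copy()
    for _ in range(n_components):
        u = Yk[:, [int(np.argmax((Yk**2).sum(0)))]]
        for _ in range(max_iter):
            w = Xk.T @ u / (u.T @ u)
            w /= np.linalg.norm(w)
            t = Xk @ w
            q = Yk.T @ t / (t.T @ t)
            u_new = Yk @ q / (q.T @ q)
            if np.linalg.norm(u_new - u) < tol * np.linalg.norm(u_new):
                u = u_new
                break
            u = u_new
        t = Xk @ w
        p = Xk.T @ t / (t.T @ t)
        q = Yk.T @ t / (t.T @ t)
        Xk = Xk - t @ p.T
        Yk = Yk - t @ q.T
        T.append(t.ravel())
        P.append(p.ravel())
    return np.column_stack(T), np.column_stack(P)
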