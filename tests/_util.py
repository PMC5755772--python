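"""Shared test helpers."""

import numpy as np

from osteomap.autocm import DistanceMatrix
from osteomap.scaling import ScaledMatrix


def scaled_from_columns(named_columns: dict[str, np.ndarray]) -> ScaledMatrix:
    """Build a complementary-encoded ScaledMatrix from raw [0,1] columns."""
    labels, cols, prov = [], [], {}
    n = None
    for name, x in named_columns.items():
        x = np.asarray(x, dtype=float)
        n = len(x)
        hi, lo = f"{name} high", f"{name} low"
        labels += [hi, lo]
        cols += [x, 1.0 - x]
        prov[hi] = (name, "high")
        prov[lo] = (name, "low")
    return ScaledMatrix(
        node_labels=labels,
        values=np.column_stack(cols),
        provenance=prov,
        record_ids=[str(i) for i in range(n)],
    )


def distance_matrix_from_dict(
    labels: list[str], entries: dict[tuple[str, str], float], default: float
) -> DistanceMatrix:
    n = len(labels)
    d = np.full((n, n), default)
    np.fill_diagonal(d, 0.0)
    for (a, b), val in entries.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = val
    return DistanceMatrix(labels=labels, d=d)


def correlated_uniform_pairs(rhos: list[float], n: int, seed: int) -> dict[str, np.ndarray]:
    """Pairs of uniform [0,1] columns with given Gaussian-copula correlations."""
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    out = {}
    for k, rho in enumerate(rhos):
        z = rng.standard_normal((n, 2))
        z[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        u = norm.cdf(z)
        out[f"p{k}a"] = u[:, 0]
        out[f"p{k}b"] = u[:, 1]
    return out
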