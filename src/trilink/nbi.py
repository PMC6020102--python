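"""Network-based inference (NBI) baseline on the SM-miRNA bipartite graph.

Two-step resource allocation: a query SM places one unit of resource on each
of its associated miRNAs; each miRNA splits its resource equally among its
associated SMs; each SM then splits its accumulated resource equally among
its own miRNAs.  The resulting per-miRNA resource is the prediction score.
In matrix form the full score matrix is ``A D_m^-1 A.T D_s^-1 A`` with
``D_m``/``D_s`` the miRNA/SM degree diagonals; zero-degree nodes contribute
nothing (0/0 -> 0).
"""

from __future__ import annotations

import numpy as np

from .types import ValidationError

__all__ = ["nbi_scores"]


def nbi_scores(A) -> np.ndarray:
    """Score every SM-miRNA pair by two-step resource allocation on ``A``.

    Rows are SMs, columns miRNAs.  An SM with no associations gets an
    all-zero score row.
    """
    A = np.asarray(getattr(A, "values", A), dtype=float)
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValidationError("NBI expects a binary association matrix")
    deg_sm = A.sum(axis=1)  # degree of each SM (its miRNA count)
    deg_mi = A.sum(axis=0)  # degree of each miRNA (its SM count)
    inv_mi = np.where(deg_mi > 0, 1.0 / np.where(deg_mi > 0, deg_mi, 1.0), 0.0)
    inv_sm = np.where(deg_sm > 0, 1.0 / np.where(deg_sm > 0, deg_sm, 1.0), 0.0)
    # step 1: miRNA -> SM redistribution; step 2: SM -> miRNA redistribution
    return (A * inv_mi[None, :]) @ A.T @ (A * inv_sm[:, None])
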