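"""Independent oracles for the test suite.

These deliberately avoid the code paths they check: the absorption
probability is obtained by solving the defining recursion as a linear system,
and fixation probabilities by solving the absorbing Markov chain directly.
"""

from __future__ import annotations

import numpy as np


def psi_linear_system(K: int, delta: float, b: float = 1.0) -> np.ndarray:
    """Absorption probabilities psi_1..psi_K of the surviving size walk,
    obtained by solving the recursion

        psi_n = delta T_n psi_{n+1} + delta (1 - T_n) psi_n

    (with T_n = b (n/K)(1 - n/K), psi_0 = 0, psi_K = 1) as a linear system.
    """
    A = np.zeros((K - 1, K - 1))
    rhs = np.zeros(K - 1)
    for row, n in enumerate(range(1, K)):
        T = b * (n / K) * (1 - n / K)
        A[row, row] = 1.0 - delta * (1.0 - T)
        if n + 1 <= K - 1:
            A[row, row + 1] = -delta * T
        else:
            rhs[row] = delta * T  # psi_K = 1
    psi = np.linalg.solve(A, rhs)
    return np.append(psi, 1.0)  # psi_1..psi_{K-1}, psi_K


def birth_death_fixation(
    Kg: int, t_down: np.ndarray, t_up: np.ndarray
) -> np.ndarray:
    """Fixation probabilities phi_0..phi_Kg of a birth-death chain on
    {0..Kg} with absorbing ends, from per-state transition probabilities
    (arrays indexed by the interior states 1..Kg-1)."""
    m = Kg - 1
    A = np.zeros((m, m))
    rhs = np.zeros(m)
    for row, i in enumerate(range(1, Kg)):
        td, tu = t_down[row], t_up[row]
        A[row, row] = td + tu
        if row > 0:
            A[row, row - 1] = -td
        if row < m - 1:
            A[row, row + 1] = -tu
        else:
            rhs[row] = tu  # phi_Kg = 1
    phi = np.linalg.solve(A, rhs)
    return np.concatenate([[0.0], phi, [1.0]])
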