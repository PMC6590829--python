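"""Machine-derived coefficient expressions for the one-Yukawa MSA
(screened-Coulomb mean spherical approximation).

Generated by scripts/derive_msa.py, a symbolic reduction of the Baxter
factorization equations; do not edit by hand."""

import numpy as np


def linear_system(Co, eta, gamma, z):
    """5x5 matrix and rhs of the linear block in (A, B, E, Ci, J)."""
    em = np.exp(-z)
    x0 = 2*eta
    x1 = 6*eta
    x2 = 12*eta
    x3 = 1/z
    x4 = x2*x3
    x5 = -x3
    x6 = em*x3
    x7 = Co*x2
    x8 = z**(-4)
    x9 = z**(-3)
    x10 = z**(-2)
    x11 = em*x10
    x12 = 6*x6
    x13 = Co*em
    x14 = em**2
    x15 = Co**2*x14
    x16 = x6*x7
    x17 = x16*(x3 + 1)
    M = np.array([
        [-x0 - 1, -x1, -x2, x4*(em - 1), 0],
        [(3/2)*eta, 4*eta - 1, x1, x4*(-em - x5 - x6), 0],
        [0, 0, 0, z, -x7],
        [eta*x13*(-12*em*x8 - 24*em*x9 - 18*x11 - x12 - 2*x3 + 12*x8 + 12*x9 - 1/2), x0*x13*(-6*em*x9 + 6*x10 - 12*x11 - x12 - 3*x3 + 6*x9 - 1), x1*x13*(-2*em*x10 + 2*x10 - 2*x6 - 1), Co*x1*x6*(-x14*x3 - x14 - x5 - 1), -x1*x15 + gamma/em],
        [1/2, 1, 1, em, 0],
    ], dtype=complex)
    b = np.array([x16 - 1, -x17, x17, -1/2*x15*z, x13], dtype=complex)
    return M, b


def tail_residual(Co, A, B, E, Ci, J, eta, gamma, z):
    """Residual of the Yukawa tail-match condition E4 (zero at a root)."""
    em = np.exp(-z)
    x0 = Co*eta
    x1 = 6*x0
    x2 = Ci*x1
    x3 = 12*x0
    x4 = E*x3
    x5 = B*x3
    x6 = A*x3
    x7 = x6/z**2
    x8 = 1/z
    x9 = x5*x8
    x10 = em**2
    return A*em*x1 - 6*Co**2*eta*x10 + Co*z + em*x4 + em*x5 + em*x6*x8 + em*x7 + em*x9 + x10*x2 - x2 - x4 - x7 - x9 + gamma/em


def contact_value(Co, A, B, E, Ci, J, eta, gamma, z):
    """Analytic g(sigma+) of the factorized solution."""
    em = np.exp(-z)
    x0 = 12*eta
    x1 = z**(-2)
    x2 = 1/z
    x3 = Ci*x0
    x4 = Co*em**2*x0
    return -1/2*A*eta - 2*B*eta + 12*Ci*eta*x1 - Co*J*em*x0 + 12*Co*em*eta*x1 + Co*em*z - 6*E*eta - em*x1*x3 - x1*x4 - x2*x3 - x2*x4 + 1


def qhat_zero(Co, A, B, E, Ci, J, eta, gamma, z):
    """Laplace transform of q at 0; S(0) = (1 - 12 eta qhat0)**-2."""
    em = np.exp(-z)
    x0 = 1/z
    x1 = Ci*x0
    return (1/6)*A + (1/2)*B + Co*em*x0 + E - em*x1 + x1
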