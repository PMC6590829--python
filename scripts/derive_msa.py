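"""Symbolic derivation of the one-Yukawa MSA solution (screened-Coulomb
structure factor) via the Baxter Wiener-Hopf factorization.

Dimensionless units: hard-core diameter sigma = 1, x = r/sigma, packing
fraction eta, screening z = kappa*sigma, contact potential gamma (kT), so
beta*u(x) = gamma * exp(-z(x-1))/x for x > 1 and the MSA closure is
c(x) = -beta*u(x) outside the core, h(x) = -1 inside.

Baxter factor-function ansatz (q continuous at x=1, exponential tail):

    q(x) = A x^2/2 + B x + E + Ci exp(-z x)      0 < x < 1
    q(x) = Co exp(-z x)                          x > 1

Baxter's relations (2*pi*rho*sigma^3 = 12 eta):

  (I)  x c(x) = -q'(x) + 12 eta Int_x^inf q'(t) q(t-x) dt
  (II) x h(x) = -q'(x) + 12 eta Int_0^inf (x-t) h(|x-t|) q(t) dt

Unknowns: A, B, E, Ci, Co and the tail moment J = Int_1^inf u h(u) e^{-zu} du.
Conditions:

  E1-E3  (II) on 0<x<1 with h = -1, coefficients of {x, 1, e^{-zx}}
  E5     e^{-zx}-projection of (II) on x>1 (J self-consistency), with the
         J*qhat(z) product linearized through E4 so the block is linear
  E7     continuity of q at x=1
  E4     Yukawa tail match of (I) on x>1:  z Co (1 - 12 eta qhat(z)) = -G,
         with G = gamma e^{z} the tail strength

{E1,E2,E3,E5,E7} are linear in (A,B,E,Ci,J) at fixed Co; eliminating them
turns E4 into a single quartic in Co -- the same closing-polynomial
structure as the classic Hayter-Penfold reduction.  The runtime solver
recovers that polynomial numerically (values of det * E4 on a complex
circle, coefficients by FFT) and takes all roots from the companion
matrix; this script generates only the small coefficient expressions.

Running it regenerates src/scatterfit/_msa_generated.py and checks the
gamma = 0 limit against the exact Percus-Yevick coefficients.
"""

from __future__ import annotations

from pathlib import Path

import sympy as sp

r, t, u = sp.symbols("r t u", positive=True)
A, B, E, Ci, Co, J = sp.symbols("A B E Ci Co J", real=True)
eta = sp.symbols("eta", positive=True)
z = sp.symbols("z", positive=True)
gamma = sp.symbols("gamma", real=True)
X = sp.symbols("X")          # stands for exp(-z*r)
em = sp.exp(-z)

G = gamma / em               # x c(x) = -G e^{-z x} for x > 1

qi = A * t**2 / 2 + B * t + E + Ci * sp.exp(-z * t)
qo = Co * sp.exp(-z * t)
qi_r = qi.subs(t, r)

unknowns = (A, B, E, Ci, J)


def integ(expr, var, lo, hi):
    return sp.integrate(expr, (var, lo, hi)).rewrite(sp.exp).expand(power_exp=True)


print("equation (II) on the core interval ...")
core_int = integ((r - t) * qi, t, 0, 1) + integ((r - t) * qo, t, 1, r + 1)
rhs = -sp.diff(qi_r, r) + 12 * eta * (-core_int - Co * sp.exp(-z * r) * J)
expr = sp.expand_power_exp(sp.expand(rhs - (-r)))
expr = expr.subs(sp.exp(-z * r - z), X * em).subs(sp.exp(-z * r), X)
poly = sp.Poly(expr, r, X)
eqs = {m: c for m, c in poly.terms()}
assert set(eqs) <= {(0, 0), (1, 0), (0, 1)}, set(eqs)
E1 = sp.expand(eqs[(1, 0)])
E2 = sp.expand(eqs[(0, 0)])
E3 = sp.expand(eqs[(0, 1)])

print("Yukawa tail match of (I) ...")
qhat_z = integ(qi * sp.exp(-z * t), t, 0, 1) + integ(qo * sp.exp(-z * t), t, 1, sp.oo)
E4 = sp.expand(z * Co * (1 - 12 * eta * qhat_z) + G)

print("e^{-zx} projection of (II) on the tail ...")
g1 = integ((r - t) * sp.exp(-z * r), r, 1, t + 1)
g2 = integ((r - t) * sp.exp(-z * r), r, t - 1, t + 1)
S2e = -(integ(qi * g1, t, 0, 1) + integ(qo * g1, t, 1, 2) + integ(qo * g2, t, 2, sp.oo))
# J (1 - 12 eta qhat(z)) = Co em^2/2 + 12 eta S2e - 12 eta Co J em^2/(2z),
# then 1 - 12 eta qhat(z) -> -G/(z Co) via E4 and multiply by -z Co:
E5 = sp.expand(J * G + z * Co * (Co * em**2 / 2 + 12 * eta * S2e)
               - 6 * eta * Co**2 * J * em**2)

E7 = A / 2 + B + E + Ci * em - Co * em

print("contact value g(1+) and qhat(0) ...")
contact = sp.expand(
    1 + z * Co * em
    - 12 * eta * (integ((1 - t) * qi, t, 0, 1) + integ((1 - t) * qo, t, 1, 2))
    - 12 * eta * Co * em * J
)
qhat0 = sp.expand(integ(qi, t, 0, 1) + integ(qo, t, 1, sp.oo))

print("verifying the Percus-Yevick limit ...")
py = {gamma: 0, Co: 0, Ci: 0, J: 0}
solPY = sp.solve([E1.subs(py), E2.subs(py), E7.subs(py)], [A, B, E], dict=True)[0]
assert sp.simplify(solPY[A] - (1 + 2 * eta) / (1 - eta) ** 2) == 0, solPY[A]
assert sp.simplify(solPY[B] + 3 * eta / (2 * (1 - eta) ** 2)) == 0, solPY[B]
gc = sp.simplify(contact.subs(py).subs(solPY))
assert sp.simplify(gc - (1 + eta / 2) / (1 - eta) ** 2) == 0, gc
# E3 and E5 must be identically satisfied in the PY limit
assert sp.simplify(E3.subs(py).subs(solPY)) == 0
assert sp.simplify(E5.subs(py).subs(solPY)) == 0
print("  PY coefficients, contact value and degenerate equations verified")

print("building the linear block M(Co) x = b ...")
M, b = sp.linear_eq_to_matrix([E1, E2, E3, E5, E7], list(unknowns))

print("generating python module ...")
EM = sp.symbols("em", positive=True)


def prep(e):
    e = sp.expand_power_exp(sp.expand(e))
    # express every exponential through em = exp(-z): exp(-k z) -> em**k
    e = e.replace(
        lambda w: w.func is sp.exp and (w.args[0] / z).is_number,
        lambda w: EM ** (-(w.args[0] / z)),
    )
    return e

L = [
    '"""Machine-derived coefficient expressions for the one-Yukawa MSA',
    "(screened-Coulomb mean spherical approximation).",
    "",
    "Generated by scripts/derive_msa.py, a symbolic reduction of the Baxter",
    'factorization equations; do not edit by hand."""',
    "",
    "import numpy as np",
    "",
]


def emit(name, args, doc, exprs, tail_builder):
    subexprs, red = sp.cse([prep(e) for e in exprs], optimizations="basic")
    L.append("")
    L.append(f"def {name}({args}):")
    L.append(f'    """{doc}"""')
    L.append("    em = np.exp(-z)")
    for s, e in subexprs:
        L.append(f"    {s} = {sp.pycode(e)}")
    L.extend(tail_builder(red))
    L.append("")


emit(
    "linear_system", "Co, eta, gamma, z",
    "5x5 matrix and rhs of the linear block in (A, B, E, Ci, J).",
    [M[i, j] for i in range(5) for j in range(5)] + list(b),
    lambda red: (
        ["    M = np.array(["]
        + [f"        [{', '.join(sp.pycode(red[5 * i + j]) for j in range(5))}],"
           for i in range(5)]
        + ["    ], dtype=complex)",
           "    b = np.array(["
           + ", ".join(sp.pycode(red[25 + i]) for i in range(5))
           + "], dtype=complex)",
           "    return M, b"]
    ),
)
emit(
    "tail_residual", "Co, A, B, E, Ci, J, eta, gamma, z",
    "Residual of the Yukawa tail-match condition E4 (zero at a root).",
    [E4], lambda red: [f"    return {sp.pycode(red[0])}"],
)
emit(
    "contact_value", "Co, A, B, E, Ci, J, eta, gamma, z",
    "Analytic g(sigma+) of the factorized solution.",
    [contact], lambda red: [f"    return {sp.pycode(red[0])}"],
)
emit(
    "qhat_zero", "Co, A, B, E, Ci, J, eta, gamma, z",
    "Laplace transform of q at 0; S(0) = (1 - 12 eta qhat0)**-2.",
    [qhat0], lambda red: [f"    return {sp.pycode(red[0])}"],
)

out = Path(__file__).resolve().parent.parent / "src" / "scatterfit" / "_msa_generated.py"
out.write_text("\n".join(L))
print(f"wrote {out} ({out.stat().st_size} bytes)")
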