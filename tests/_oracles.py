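"""Independent oracles used by the test suite.

The symbolic Euler-Lagrange oracle derives the three-link-on-moving-base
equations of motion from scratch with sympy (energies -> Lagrange equations
-> linear solve for the accelerations) and is kept fully separate from the
hand-coded closed-form dynamics in the package.
"""

from __future__ import annotations

import numpy as np
import sympy as sp


def build_lagrangian_oracle():
    """Return f(m, L, d, Ic, g, alpha, alphadot, tau_joint, ap) -> alphadd.

    All arguments are length-3 sequences except g and ap.  ``tau_joint`` are
    joint torques (ankle, knee, hip); angles are absolute segment angles
    from vertical.
    """
    t = sp.Symbol("t")
    m = sp.symbols("m1:4", positive=True)
    L = sp.symbols("L1:4", positive=True)
    d = sp.symbols("d1:4", positive=True)
    Ic = sp.symbols("I1:4", positive=True)
    g = sp.Symbol("g", positive=True)
    tau = sp.symbols("tau1:4")
    xp = sp.Function("xp")(t)
    al = [sp.Function(f"alpha{i}")(t) for i in range(3)]

    T = sp.Integer(0)
    V = sp.Integer(0)
    jx, jz = xp, sp.Integer(0)
    for k in range(3):
        cx = jx + d[k] * sp.sin(al[k])
        cz = jz + d[k] * sp.cos(al[k])
        vx, vz = sp.diff(cx, t), sp.diff(cz, t)
        T += m[k] * (vx**2 + vz**2) / 2 + Ic[k] * sp.diff(al[k], t) ** 2 / 2
        V += m[k] * g * cz
        jx = jx + L[k] * sp.sin(al[k])
        jz = jz + L[k] * sp.cos(al[k])
    Lag = T - V
    # joint-space virtual work: phi = (a1, a2-a1, a3-a2)
    Q = [tau[0] - tau[1], tau[1] - tau[2], tau[2]]
    eqs = []
    for i in range(3):
        adot_i = sp.diff(al[i], t)
        eqs.append(sp.diff(sp.diff(Lag, adot_i), t) - sp.diff(Lag, al[i]) - Q[i])

    a_s = sp.symbols("a1:4")
    ad_s = sp.symbols("ad1:4")
    add_s = sp.symbols("add1:4")
    vp, ap = sp.symbols("vp ap")
    subs = {sp.diff(xp, t, 2): ap, sp.diff(xp, t): vp, xp: 0}
    for i in range(3):
        subs[sp.diff(al[i], t, 2)] = add_s[i]
        subs[sp.diff(al[i], t)] = ad_s[i]
        subs[al[i]] = a_s[i]
    eqs = [sp.expand(e.subs(subs)) for e in eqs]
    Msym, rsym = sp.linear_eq_to_matrix(eqs, add_s)
    args = (*m, *L, *d, *Ic, g, *a_s, *ad_s, *tau, vp, ap)
    fM = sp.lambdify(args, Msym, modules="numpy")
    fr = sp.lambdify(args, rsym, modules="numpy")

    def oracle(mv, Lv, dv, Icv, gv, alpha, alphadot, tau_joint, platform_acc):
        vals = (*mv, *Lv, *dv, *Icv, gv, *alpha, *alphadot, *tau_joint, 0.0, platform_acc)
        Mn = np.asarray(fM(*vals), dtype=float)
        rn = np.asarray(fr(*vals), dtype=float).ravel()
        return np.linalg.solve(Mn, rn)

    return oracle


def alphadd_from_model(model, phi, phidot, tau, ap, oracle):
    """Evaluate the symbolic oracle for a package anthropometric model."""
    la = model.link_arrays
    S = np.tril(np.ones((3, 3)))
    alpha = S @ np.asarray(phi, float)
    alphadot = S @ np.asarray(phidot, float)
    add = oracle(la["m"], la["L"], la["d"], la["Ic"], model.gravity,
                 alpha, alphadot, np.asarray(tau, float), ap)
    D = np.array([[1.0, 0, 0], [-1.0, 1.0, 0], [0, -1.0, 1.0]])
    return D @ add
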