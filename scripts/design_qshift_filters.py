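"""Design an even-length orthonormal lowpass filter with ~quarter-sample
offset group delay (q-shift) via a paraunitary lattice parameterization.

The lattice guarantees exact orthonormality for any angle vector; the
optimization only shapes the response (lowpass + linear phase with delay
(L-1)/2 - 1/4).  Best result is printed for freezing into the package.
"""
import numpy as np
from scipy.optimize import minimize


def lattice_filters(thetas):
    """Polyphase lattice -> (h0, h1) orthonormal pair of length 2*len(thetas)."""
    c, s = np.cos(thetas[0]), np.sin(thetas[0])
    P = np.zeros((2, 2, 1))
    P[:, :, 0] = [[c, -s], [s, c]]
    for th in thetas[1:]:
        c, s = np.cos(th), np.sin(th)
        Q = np.zeros((2, 2, P.shape[2] + 1))
        # delay second row by one (Lambda(z)), then rotate
        row0 = np.concatenate([P[0], np.zeros((2, 1))], axis=1)
        row1 = np.concatenate([np.zeros((2, 1)), P[1]], axis=1)
        Q[0] = c * row0 - s * row1
        Q[1] = s * row0 + c * row1
        P = Q
    d = P.shape[2]
    h0 = np.zeros(2 * d)
    h1 = np.zeros(2 * d)
    h0[0::2] = P[0, 0]
    h0[1::2] = P[0, 1]
    h1[0::2] = P[1, 0]
    h1[1::2] = P[1, 1]
    return h0, h1


def check_orthonormal(h):
    L = len(h)
    errs = []
    for j in range(1, L // 2):
        errs.append(abs(np.dot(h[: L - 2 * j], h[2 * j :])))
    errs.append(abs(np.dot(h, h) - 1.0))
    return max(errs)


def objective(thetas, L, wpass=0.55, wstop=0.7):
    h0, _ = lattice_filters(thetas)
    w = np.linspace(0, np.pi, 512)
    E = np.exp(-1j * np.outer(w, np.arange(L)))
    H = E @ h0
    d = (L - 1) / 2.0 - 0.25
    mag = np.abs(H)
    passband = w <= wpass * np.pi
    stop = w >= wstop * np.pi
    J = np.sum(np.abs(H[passband] * np.exp(1j * w[passband] * d) - mag[passband]) ** 2)
    J += 1e6 * abs(np.sum(h0 * (-1.0) ** np.arange(L))) ** 2  # vanishing moment
    J += 0.5 * np.sum(mag[stop] ** 2)
    return J


def design(L=10, n_starts=80, seed=0):
    m = L // 2
    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_starts):
        x0 = rng.uniform(-np.pi, np.pi, m)
        res = minimize(objective, x0, args=(L,), method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-12, "fatol": 1e-14})
        res = minimize(objective, res.x, args=(L,), method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-13, "fatol": 1e-15})
        if best is None or res.fun < best.fun:
            best = res
    h0, h1 = lattice_filters(best.x)
    if h0[np.argmax(np.abs(h0))] < 0:
        h0 = -h0
    return h0, best


if __name__ == "__main__":
    for L in (10, 14):
        h0, res = design(L)
        print(f"L={L}  J={res.fun:.3e}  orth_err={check_orthonormal(h0):.2e}")
        w = np.linspace(1e-3, np.pi, 2049)
        H = np.exp(-1j * np.outer(w, np.arange(L))) @ h0
        ph = np.unwrap(np.angle(H))
        gd = -np.gradient(ph, w)
        sel = w < 0.5 * np.pi
        print("  H(0):", abs(H[0] if w[0]==0 else np.sum(h0)), " H(pi):", abs(np.exp(-1j*np.pi*np.arange(L)) @ h0))
        print("  target delay:", (L - 1) / 2 - 0.25, " mean gd in passband:", gd[sel].mean(),
              " gd ripple:", gd[sel].std())
        print("  h0 =", np.array2string(h0, precision=16, separator=", "))
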