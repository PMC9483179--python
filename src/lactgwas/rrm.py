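"""Single-trait random-regression test-day model fitted by REML.

Model for a test-day record of cow l at DIM t:

    y = HTD + Age + Season + phi(t)' a_l + phi(t)' p_l + e

with phi the (normalized) Legendre covariates, a_l ~ additive genetic and
p_l ~ permanent-environment regression coefficient vectors, and

    Var[a; p; e] = [A (x) G, 0, 0; 0, I (x) P, 0; 0, 0, I sigma_e2]

(animal-major stacking; A the numerator relationship matrix).  Variance
components are estimated by EM-REML with optional average-information (AI)
acceleration: an AI (quasi-Newton) step is attempted each round and accepted
only if it increases the restricted likelihood, otherwise the guaranteed
monotone EM step is taken.  Estimated G and P are projected onto the PSD cone
after every update.

DIM-specific quantities follow from the coefficient covariances:
additive variance phi' G phi, permanent-environment variance phi' P phi,
heritability h2(t) and the genetic correlation surface r(t1, t2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse
from sklearn.base import BaseEstimator

from .basis import LegendreBasis
from .pedigree import Pedigree, nrm_inverse

DEFAULT_FIXED_FACTORS = ("htd", "age_class", "season_class")
DEFAULT_DIM_GRID = (7, 35, 50, 140, 280)


@dataclass
class VarianceComponents:
    """Coefficient-scale covariances: G (additive), P (permanent env.), sigma_e2."""

    G: np.ndarray
    P: np.ndarray
    sigma_e2: float

    def __post_init__(self):
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        if self.G.shape != self.P.shape or self.G.shape[0] != self.G.shape[1]:
            raise ValueError("G and P must be square matrices of equal size")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")

    @property
    def n_coef(self) -> int:
        return self.G.shape[0]

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(self.G.copy(), self.P.copy(), float(self.sigma_e2))


@dataclass
class RRMFit:
    components: VarianceComponents
    basis: LegendreBasis
    animal_ids: np.ndarray
    cow_ids: np.ndarray
    a_hat: np.ndarray  # (n_animals, k)
    p_hat: np.ndarray  # (n_cows, k)
    fixed_solutions: pd.Series
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))

    def ebv(self, animal, dim):
        return ebv_at_dim(self, self.basis, animal, dim)


# ---------------------------------------------------------------------------
# DIM-specific summaries


def variance_at(components: VarianceComponents, basis: LegendreBasis, dim):
    """(additive, permanent-environment, phenotypic) variance at a DIM."""
    phi = basis.row(dim)
    v_a = float(phi @ components.G @ phi)
    v_pe = float(phi @ components.P @ phi)
    return v_a, v_pe, v_a + v_pe + components.sigma_e2


def heritability_curve(components: VarianceComponents, basis: LegendreBasis,
                       dims=DEFAULT_DIM_GRID) -> pd.Series:
    """h2(t) = phi'G phi / (phi'G phi + phi'P phi + sigma_e2) per DIM."""
    out = {}
    for d in dims:
        v_a, v_pe, v_p = variance_at(components, basis, d)
        if v_p <= 0:
            raise ValueError(f"zero phenotypic variance at DIM {d}")
        out[d] = v_a / v_p
    return pd.Series(out, name="h2")


def genetic_correlation(components: VarianceComponents, basis: LegendreBasis,
                        dim1, dim2) -> float:
    """r(t1,t2) = phi1'G phi2 / sqrt(phi1'G phi1 * phi2'G phi2)."""
    p1, p2 = basis.row(dim1), basis.row(dim2)
    v1 = float(p1 @ components.G @ p1)
    v2 = float(p2 @ components.G @ p2)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("zero additive variance at one of the DIMs")
    return float(p1 @ components.G @ p2) / np.sqrt(v1 * v2)


def genetic_correlation_grid(components, basis, dims=DEFAULT_DIM_GRID) -> pd.DataFrame:
    n = len(dims)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = genetic_correlation(components, basis, dims[i], dims[j])
    return pd.DataFrame(M, index=list(dims), columns=list(dims))


def ebv_at_dim(fit: RRMFit, basis: LegendreBasis, animal, dim) -> float:
    """DIM-specific EBV: phi(dim)' a_hat for one animal."""
    idx = np.flatnonzero(fit.animal_ids == animal)
    if len(idx) == 0:
        raise KeyError(f"unknown animal {animal!r}")
    return float(basis.row(dim) @ fit.a_hat[idx[0]])


def ebv_table(fit: RRMFit, dims=DEFAULT_DIM_GRID, animals=None) -> pd.DataFrame:
    """EBV trajectories phi(t)'a_hat for all (or selected) animals."""
    ids = fit.animal_ids if animals is None else np.asarray(animals)
    pos = {a: i for i, a in enumerate(fit.animal_ids)}
    A = fit.a_hat[[pos[a] for a in ids]]
    out = pd.DataFrame({"animal_id": ids})
    for d in dims:
        out[f"ebv_dim{d}"] = A @ fit.basis.row(d)
    return out


# ---------------------------------------------------------------------------
# Mixed-model equations


def _fixed_design(records: pd.DataFrame, factors, on_singular="raise"):
    """Full-rank fixed-effect design: first factor keeps all levels, later
    factors drop their first level as reference.

    Remaining aliased (confounded) columns are detected by pivoted QR and
    either reported in an error or dropped with a warning, depending on
    ``on_singular`` ("raise" or "drop")."""
    cols, names = [], []
    for fi, f in enumerate(factors):
        levels = sorted(records[f].astype(str).unique())
        use = levels if fi == 0 else levels[1:]
        codes = pd.Categorical(records[f].astype(str), categories=levels).codes
        for lv in use:
            names.append(f"{f}={lv}")
        base = np.zeros((len(records), len(levels)))
        base[np.arange(len(records)), codes] = 1.0
        cols.append(base if fi == 0 else base[:, 1:])
    X = np.hstack(cols) if cols else np.ones((len(records), 1))
    R, piv = linalg.qr(X, mode="r", pivoting=True)
    d = np.abs(np.diag(R))
    rank = int(np.sum(d > 1e-8 * max(1.0, d.max())))
    if rank < X.shape[1]:
        aliased = sorted(names[i] for i in piv[rank:])
        if on_singular == "raise":
            raise ValueError(f"confounded fixed-effect levels: {aliased}")
        warnings.warn(
            f"dropping {len(aliased)} confounded fixed-effect level(s): "
            f"{aliased[:5]}{'...' if len(aliased) > 5 else ''}"
        )
        keep = np.sort(piv[:rank])
        X = X[:, keep]
        names = [names[i] for i in keep]
    return X, names


class MMESystem:
    """Henderson's mixed-model equations for the random-regression model.

    Holds the design matrices and pedigree pieces; ``solve`` assembles the
    coefficient matrix for given variance components (ridge terms
    A^-1 (x) G^-1 and I (x) P^-1) and returns solutions and, optionally, the
    pieces REML needs.
    """

    def __init__(self, records: pd.DataFrame, ped: Pedigree, basis: LegendreBasis,
                 value_col: str = "value", factors=DEFAULT_FIXED_FACTORS,
                 on_singular: str = "raise"):
        records = records.reset_index(drop=True)
        self.basis = basis
        k = basis.n_coef
        self.k = k
        # prune animals that carry no information: no records and not an
        # ancestor of a recorded cow (their BLUPs are parent averages and are
        # reconstructed after solving)
        self.full_animal_ids = ped.animal_ids.copy()
        self.full_parents = ped.parent_indices()
        full_pos = {a: i for i, a in enumerate(self.full_animal_ids)}
        missing = set(records["cow_id"]) - set(full_pos)
        if missing:
            raise ValueError(f"cows missing from pedigree: {sorted(missing)[:5]}")
        keep = np.zeros(len(ped), dtype=bool)
        stack = [full_pos[c] for c in records["cow_id"].unique()]
        while stack:
            i = stack.pop()
            if keep[i]:
                continue
            keep[i] = True
            for p in self.full_parents[i]:
                if p >= 0 and not keep[p]:
                    stack.append(p)
        self.kept_mask = keep
        ped = Pedigree(ped.entries[keep].reset_index(drop=True))
        self.animal_ids = ped.animal_ids.copy()
        apos = {a: i for i, a in enumerate(self.animal_ids)}
        self.cow_ids = np.array(sorted(records["cow_id"].unique()))
        cpos = {c: i for i, c in enumerate(self.cow_ids)}
        self.q = len(self.animal_ids)
        self.n_cows = len(self.cow_ids)

        y = records[value_col].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"missing values in {value_col!r}")
        X, self.fixed_names = _fixed_design(records, factors, on_singular)
        self.p = X.shape[1]
        N = len(records)
        Phi = basis.row(records["dim"].to_numpy())

        arow = records["cow_id"].map(apos).to_numpy()
        crow = records["cow_id"].map(cpos).to_numpy()
        ii = np.repeat(np.arange(N), k)
        ja = (arow[:, None] * k + np.arange(k)).ravel()
        jc = (crow[:, None] * k + np.arange(k)).ravel()
        Za = sparse.csr_matrix((Phi.ravel(), (ii, ja)), shape=(N, self.q * k))
        Zp = sparse.csr_matrix((Phi.ravel(), (ii, jc)), shape=(N, self.n_cows * k))

        self.N = N
        self.y = y
        self.X = X
        self.Phi = Phi
        self.crow = crow
        self.Za = Za
        self.Zp = Zp
        self.yty = float(y @ y)
        self.Ainv = nrm_inverse(ped)
        self.logdet_A = -_sparse_logdet(self.Ainv)
        self.off_a = self.p
        self.off_p = self.p + self.q * k
        self.M = self.off_p + self.n_cows * k
        # pieces for the PE-absorbed (Schur complement) system: the
        # permanent-environment block is block-diagonal per cow and is
        # eliminated exactly, leaving a dense system in fixed + additive
        # equations only
        self.M_top = self.off_p
        self.W_top = sparse.hstack([sparse.csr_matrix(X), Za], format="csr")
        self.WtopT_Wtop = (self.W_top.T @ self.W_top).toarray()
        self.Wtop_ty = self.W_top.T @ y
        self.Zp_ty = Zp.T @ y
        self.B0 = (self.W_top.T @ Zp).tocsr()  # W_top' Zp (sparse)
        Gcow = np.zeros((self.n_cows, k, k))
        np.add.at(Gcow, crow, Phi[:, :, None] * Phi[:, None, :])
        self.Gcow = Gcow

    def expand_a(self, a_hat: np.ndarray) -> np.ndarray:
        """Coefficient solutions for every pedigree animal: pruned animals
        (no records, no recorded descendants) get the parent average, which is
        their exact BLUP."""
        full = np.zeros((len(self.full_animal_ids), self.k))
        kept_rows = np.flatnonzero(self.kept_mask)
        full[kept_rows] = a_hat
        for i in range(len(full)):
            if self.kept_mask[i]:
                continue
            s, d = self.full_parents[i]
            acc = np.zeros(self.k)
            if s >= 0:
                acc += 0.5 * full[s]
            if d >= 0:
                acc += 0.5 * full[d]
            full[i] = acc
        return full

    def coefficient_matrix(self, comp: VarianceComponents) -> np.ndarray:
        """Full dense MME coefficient matrix C = W'W/sigma_e2 + ridge blocks
        (reference form; ``solve`` works on the PE-absorbed system)."""
        Ginv = _pd_inverse(comp.G, "G")
        Pinv = _pd_inverse(comp.P, "P")
        W = sparse.hstack([sparse.csr_matrix(self.X), self.Za, self.Zp], format="csr")
        C = (W.T @ W).toarray() / comp.sigma_e2
        sa = slice(self.off_a, self.off_p)
        sp = slice(self.off_p, self.M)
        C[sa, sa] += sparse.kron(self.Ainv, Ginv).toarray()
        C[sp, sp] += np.kron(np.eye(self.n_cows), Pinv)
        return C

    def _block_diag(self, blocks: np.ndarray):
        """Sparse block-diagonal matrix from an (n, k, k) stack."""
        n, k, _ = blocks.shape
        base = np.arange(n)[:, None, None] * k
        rows = (base + np.broadcast_to(np.arange(k)[:, None], (k, k))).ravel()
        cols = (base + np.broadcast_to(np.arange(k)[None, :], (k, k))).ravel()
        return sparse.csr_matrix((blocks.ravel(), (rows, cols)),
                                 shape=(n * k, n * k))

    def solve(self, comp: VarianceComponents, want_inverse: bool = False):
        """Solve the MME via exact absorption of the PE block.

        Returns solutions and the restricted log-likelihood; with
        ``want_inverse`` also the REML trace accumulations (C^aa at the A^-1
        pattern; summed diagonal PE blocks of the full C inverse) and a
        solver closure for products with the full C inverse.
        """
        se2 = comp.sigma_e2
        Ginv = _pd_inverse(comp.G, "G")
        Pinv = _pd_inverse(comp.P, "P")
        k, q, n = self.k, self.q, self.n_cows
        sa = slice(self.p, self.M_top)

        C_red = self.WtopT_Wtop / se2
        C_red[sa, sa] += sparse.kron(self.Ainv, Ginv).toarray()
        D = self.Gcow / se2 + Pinv[None, :, :]
        cholD = np.linalg.cholesky(D)
        logdet_D = 2.0 * float(np.log(
            cholD[:, np.arange(k), np.arange(k)]).sum())
        Dinv = np.linalg.inv(D)
        Dbd = self._block_diag(Dinv)
        BD = self.B0 @ Dbd  # W_top' Zp D^-1, sparse
        C_red -= (BD @ self.B0.T).toarray() / (se2 * se2)

        cho = linalg.cho_factor(C_red, lower=True, check_finite=False)
        r_top = self.Wtop_ty / se2
        r_p = self.Zp_ty / se2
        rhs = r_top - (BD @ r_p) / se2
        theta_top = linalg.cho_solve(cho, rhs, check_finite=False)
        p_vec = Dbd @ (r_p - (self.B0.T @ theta_top) / se2)
        ypy = self.yty / se2 - (r_top @ theta_top + r_p @ p_vec)
        logdet_C = 2.0 * np.sum(np.log(np.diag(cho[0]))) + logdet_D
        m2ll = (
            self.N * np.log(se2)
            + k * self.logdet_A
            + q * _logdet(comp.G)
            + n * _logdet(comp.P)
            + logdet_C
            + ypy
        )
        out = {
            "theta_top": theta_top,
            "beta": theta_top[: self.p],
            "a_hat": theta_top[self.p :].reshape(q, k),
            "p_hat": p_vec.reshape(n, k),
            "loglik": -0.5 * m2ll,
            "ypy": ypy,
        }
        if want_inverse:
            c, info = linalg.lapack.dpotri(cho[0], lower=1)
            if info != 0:
                raise np.linalg.LinAlgError("dpotri failed")
            Cinv_red = np.tril(c) + np.tril(c, -1).T
            Caa = Cinv_red[sa, sa]
            S_tr = np.zeros((k, k))
            coo = self.Ainv.tocoo()
            for i, j, v in zip(coo.row, coo.col, coo.data):
                S_tr += v * Caa[i * k : (i + 1) * k, j * k : (j + 1) * k]
            # C^pp diagonal blocks: D^-1 + (D^-1 B') C_red^-1 (B D^-1)
            E2 = (BD.T / se2).tocsr()  # D^-1 B', nk x M_top
            F2 = E2 @ Cinv_red
            Bsum = Dinv.sum(axis=0)
            for l in range(n):
                El = E2[l * k : (l + 1) * k]
                Bsum += (El @ F2[l * k : (l + 1) * k].T).T
            out["S_tr"] = S_tr
            out["Bsum"] = Bsum

            def solve_full(b_top, b_p):
                """z = C^-1 b for the full (unabsorbed) system."""
                z_top = linalg.cho_solve(
                    cho, b_top - (BD @ b_p) / se2, check_finite=False)
                z_p = Dbd @ (b_p - (self.B0.T @ z_top) / se2)
                return z_top, z_p

            out["solve_full"] = solve_full
        return out


def build_mme(records, ped, basis, components=None, value_col="value",
              factors=DEFAULT_FIXED_FACTORS, on_singular="raise") -> MMESystem:
    """Assemble the mixed-model equation system (thin constructor wrapper)."""
    return MMESystem(records, ped, basis, value_col=value_col, factors=factors,
                     on_singular=on_singular)


def _sparse_logdet(Aspr) -> float:
    lu = sparse.linalg.splu(Aspr.tocsc(), permc_spec="NATURAL", diag_pivot_thresh=0)
    d = lu.U.diagonal()
    if np.any(d <= 0):  # fall back to dense for safety
        return float(np.linalg.slogdet(Aspr.toarray())[1])
    return float(np.sum(np.log(d)))


def _logdet(M) -> float:
    sign, v = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PD covariance in logdet")
    return float(v)


def _pd_inverse(M, name):
    try:
        return linalg.inv(M, check_finite=False)
    except linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"{name} not invertible") from e


def project_psd(M: np.ndarray, floor_rel: float = 1e-10) -> np.ndarray:
    """Nearest-PSD projection with a tiny eigenvalue floor (keeps C solvable)."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    floor = floor_rel * max(1.0, float(np.abs(w).max()))
    return (V * np.maximum(w, floor)) @ V.T


# ---------------------------------------------------------------------------
# REML


def _vech_indices(k):
    return [(i, j) for i in range(k) for j in range(i, k)]


def _trace_pieces(sys: MMESystem, sol):
    """Trace accumulations (computed inside ``solve(want_inverse=True)``)."""
    return sol["S_tr"], sol["Bsum"]


def _em_update(sys: MMESystem, comp: VarianceComponents, sol, pieces=None):
    """One EM-REML update of (G, P, sigma_e2) from current MME solutions."""
    k, q, n = sys.k, sys.q, sys.n_cows
    Ahat, Phat = sol["a_hat"], sol["p_hat"]
    S_tr, Bsum = pieces if pieces is not None else _trace_pieces(sys, sol)
    G_new = (Ahat.T @ (sys.Ainv @ Ahat) + S_tr) / q
    P_new = (Phat.T @ Phat + Bsum) / n
    # y'y - theta'W'y = sigma_e2 * y'Py
    sigma_new = comp.sigma_e2 * sol["ypy"] / (sys.N - sys.p)
    return VarianceComponents(project_psd(G_new), project_psd(P_new),
                              max(float(sigma_new), 1e-12))


def _ai_update(sys: MMESystem, comp: VarianceComponents, sol, pieces):
    """Average-information (quasi-Newton) update; may propose an invalid step —
    the caller validates against the restricted likelihood."""
    k, q, n = sys.k, sys.q, sys.n_cows
    Ginv = _pd_inverse(comp.G, "G")
    Pinv = _pd_inverse(comp.P, "P")
    se2 = comp.sigma_e2

    resid = (sys.y - sys.X @ sol["beta"]
             - sys.Za @ sol["a_hat"].ravel()
             - sys.Zp @ sol["p_hat"].ravel())
    Py = resid / se2
    Ta = (sys.Za.T @ Py).reshape(q, k)
    Tp = (sys.Zp.T @ Py).reshape(n, k)
    if not hasattr(sys, "_A_dense"):
        sys._A_dense = np.linalg.inv(sys.Ainv.toarray())
    ATa = sys._A_dense @ Ta

    idx = _vech_indices(k)
    npar = 2 * len(idx) + 1

    def _E(i, j):
        E = np.zeros((k, k))
        E[i, j] = E[j, i] = 1.0
        return E

    F = np.empty((sys.N, npar))
    for col, (i, j) in enumerate(idx):
        F[:, col] = sys.Za @ (ATa @ _E(i, j)).ravel()
    for col, (i, j) in enumerate(idx):
        F[:, len(idx) + col] = sys.Zp @ (Tp @ _E(i, j)).ravel()
    F[:, -1] = Py

    z_top, z_p = sol["solve_full"](sys.W_top.T @ F / se2, sys.Zp.T @ F / se2)
    PF = (F - sys.W_top @ z_top - sys.Zp @ z_p) / se2
    AI = 0.5 * (F.T @ PF)

    # gradient of the restricted log-likelihood, via C-inverse trace identities
    S_tr, Bsum = pieces
    Dsum_a = S_tr @ Ginv
    Dsum_p = Bsum @ Pinv
    g = np.empty(npar)
    for col, (i, j) in enumerate(idx):
        trPV = q * np.trace(_E(i, j) @ Ginv) - np.trace(_E(i, j) @ Ginv @ Dsum_a)
        g[col] = -0.5 * (trPV - F[:, col] @ Py)
    for col, (i, j) in enumerate(idx):
        c = len(idx) + col
        trPV = n * np.trace(_E(i, j) @ Pinv) - np.trace(_E(i, j) @ Pinv @ Dsum_p)
        g[c] = -0.5 * (trPV - F[:, c] @ Py)
    # tr(P) via tr(C^-1 W'W)/se2 = M - tr(C^-1 Sigma^-1)
    trP = (sys.N - sys.M + np.trace(Dsum_a) + np.trace(Dsum_p)) / se2
    g[-1] = -0.5 * (trP - Py @ Py)

    # Newton/AI step taken in the Cholesky parametrization (G = L L'), so any
    # step stays inside the PSD cone — essential when the REML optimum has a
    # singular G or P.  The vech-space gradient/AI are mapped through the
    # Jacobian of G w.r.t. the lower-triangular factor.
    LG = _psd_cholesky(comp.G)
    LP = _psd_cholesky(comp.P)
    TG = _chol_jacobian(LG, idx)
    TP = _chol_jacobian(LP, idx)
    nL = len(idx)
    T = np.zeros((npar, 2 * nL + 1))
    T[:nL, :nL] = TG
    T[nL : 2 * nL, nL : 2 * nL] = TP
    T[-1, -1] = 1.0
    gL = T.T @ g
    AIL = T.T @ AI @ T
    # truncated eigen-solve: at a PSD boundary some factor directions carry no
    # information (singular AI); step only in well-conditioned directions
    w, V = np.linalg.eigh(0.5 * (AIL + AIL.T))
    keep = w > 1e-8 * max(w.max(), 1e-30)
    if not keep.any():
        return None
    step = V[:, keep] @ ((V[:, keep].T @ gL) / w[keep])
    return {"step": step, "LG": LG, "LP": LP}


def _psd_cholesky(M: np.ndarray) -> np.ndarray:
    """Lower-triangular factor of a PSD matrix (pivot-free, eigen fallback)."""
    try:
        return np.linalg.cholesky(M + 1e-12 * np.trace(M) * np.eye(len(M)))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        S = (V * np.sqrt(np.clip(w, 0, None))) @ V.T
        _, r = np.linalg.qr(S)
        return r.T

def _chol_jacobian(L: np.ndarray, idx) -> np.ndarray:
    """Map from lower-triangular-factor perturbations to vech(G) coordinates.

    For G = L L', a unit perturbation of L[a,b] changes G by
    e_a (L e_b)' + (L e_b) e_a'; column (a,b) holds its coefficients on the
    symmetric basis {E_ij} indexed like ``idx``."""
    k = L.shape[0]
    cols = [(a, b) for a in range(k) for b in range(a + 1)]  # lower triangle
    T = np.zeros((len(idx), len(cols)))
    for c, (a, b) in enumerate(cols):
        lb = L[:, b]
        dG = np.zeros((k, k))
        dG[a, :] += lb
        dG[:, a] += lb
        for r, (i, j) in enumerate(idx):
            T[r, c] = dG[i, j]
    return T


def _apply_step(comp: VarianceComponents, step_info: dict, scale: float):
    """Components at a scaled AI step in Cholesky coordinates; None if invalid."""
    k = comp.n_coef
    nL = k * (k + 1) // 2
    step = step_info["step"]
    cols = [(a, b) for a in range(k) for b in range(a + 1)]
    LG = step_info["LG"].copy()
    LP = step_info["LP"].copy()
    for c, (a, b) in enumerate(cols):
        LG[a, b] += scale * step[c]
        LP[a, b] += scale * step[nL + c]
    se2_new = comp.sigma_e2 + scale * step[-1]
    if se2_new <= 0:
        return None
    G_new = LG @ LG.T
    P_new = LP @ LP.T
    # hair-thin ridge keeps the MME ridge blocks invertible at the boundary
    G_new += 1e-10 * max(np.trace(G_new), 1e-6) * np.eye(k)
    P_new += 1e-10 * max(np.trace(P_new), 1e-6) * np.eye(k)
    return VarianceComponents(G_new, P_new, float(se2_new))


def moment_start(sys_: MMESystem, ped: Pedigree) -> VarianceComponents | None:
    """Method-of-moments starting values for REML.

    Fixed effects are removed by OLS; each cow's residual trajectory is
    regressed on the basis, giving coefficient estimates b_c with
    Cov(b_A, b_B) = a_AB G between relatives and
    Cov(b_c, b_c) = G + P + sigma_e2 (Phi'Phi)^-1 within cow.  Cross-products
    over related pairs identify G; the within-cow moment then gives P.
    Returns None when the data cannot support the moments (few records or no
    related pairs) — the caller falls back to a generic start.
    """
    k = sys_.k
    X, y, Phi, crow = sys_.X, sys_.y, sys_.Phi, sys_.crow
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    res = y - X @ beta
    n_cows = sys_.n_cows
    b = np.full((n_cows, k), np.nan)
    se2_num = se2_den = 0.0
    inv_mean = np.zeros((k, k))
    n_used = 0
    for c in range(n_cows):
        rows = np.flatnonzero(crow == c)
        if len(rows) < k + 2:
            continue
        Pc = Phi[rows]
        G_ = Pc.T @ Pc
        try:
            Gi = np.linalg.inv(G_)
        except np.linalg.LinAlgError:
            continue
        bc = Gi @ (Pc.T @ res[rows])
        b[c] = bc
        e = res[rows] - Pc @ bc
        se2_num += float(e @ e)
        se2_den += len(rows) - k
        inv_mean += Gi
        n_used += 1
    if n_used < 10 or se2_den <= 0:
        return None
    se2 = se2_num / se2_den
    inv_mean /= n_used

    # additive covariance from cross-products of related cows' coefficients
    cows_full = np.array([np.flatnonzero(sys_.animal_ids == c)[0] for c in sys_.cow_ids])
    A = np.linalg.inv(sys_.Ainv.toarray())[np.ix_(cows_full, cows_full)]
    iu, ju = np.triu_indices(n_cows, 1)
    rel = A[iu, ju]
    ok = (rel >= 0.2) & ~np.isnan(b[iu, 0]) & ~np.isnan(b[ju, 0])
    if ok.sum() < 10:
        return None
    iu, ju, rel = iu[ok], ju[ok], rel[ok]
    S = np.zeros((k, k))
    for a_ij, bi, bj in zip(rel, b[iu], b[ju]):
        S += a_ij * 0.5 * (np.outer(bi, bj) + np.outer(bj, bi))
    G0 = S / np.sum(rel**2)
    used = ~np.isnan(b[:, 0])
    Cb = np.cov(b[used].T) if used.sum() > 1 else np.eye(k)
    Cb = np.atleast_2d(Cb)
    P0 = Cb - G0 - se2 * inv_mean
    floor = 1e-3 * max(np.trace(Cb) / k, 1e-6)
    G0 = project_psd(G0, 1e-6) + floor * np.eye(k)
    P0 = project_psd(P0, 1e-6) + floor * np.eye(k)
    return VarianceComponents(G0, P0, max(se2, 1e-8))


def reml_fit(records: pd.DataFrame, ped: Pedigree, basis: LegendreBasis,
             init: VarianceComponents | None = None, value_col: str = "value",
             factors=DEFAULT_FIXED_FACTORS, tol: float = 1e-6,
             max_iter: int = 500, use_ai: bool = True,
             verbose: bool = False) -> RRMFit:
    """Fit the random-regression model by (AI-accelerated) EM-REML.

    Non-convergence is reported via ``converged=False`` on the result, not an
    exception; components at a boundary are floored, not failed.
    """
    sys_ = build_mme(records, ped, basis, value_col=value_col, factors=factors,
                     on_singular="drop")
    k = basis.n_coef
    if init is None:
        init = moment_start(sys_, ped)
    if init is None:
        vy = float(np.var(sys_.y))
        scale = vy / 3.0
        init = VarianceComponents(scale * np.eye(k) / k * 2.0,
                                  scale * np.eye(k) / k * 2.0, scale)
    comp = init.copy()
    sol = sys_.solve(comp, want_inverse=True)
    path = [sol["loglik"]]
    converged = False
    n_done = 0
    for it in range(1, max_iter + 1):
        n_done = it
        pieces = _trace_pieces(sys_, sol)
        step = _ai_update(sys_, comp, sol, pieces) if use_ai else None
        new_comp, new_sol = None, None
        used_scale = None
        if step is not None:
            # backtracking line search along the AI direction; heavily damped
            # AI steps are worse than an EM/SQUAREM cycle, so only accept
            # near-full steps here
            for scale in (1.0, 0.5):
                cand = _apply_step(comp, step, scale)
                if cand is None:
                    continue
                try:
                    trial_ll = sys_.solve(cand)["loglik"]
                except (np.linalg.LinAlgError, linalg.LinAlgError):
                    continue
                if trial_ll >= sol["loglik"] + 1e-10:
                    new_comp = cand
                    used_scale = scale
                    break
        if new_comp is not None:
            new_sol = sys_.solve(new_comp, want_inverse=True)
        else:
            # EM with squared extrapolation (handles the slow G-vs-P manifold
            # and PSD-boundary optima where Newton-type steps fail)
            new_comp, new_sol = _squarem_cycle(sys_, comp, sol)
        delta = _param_change(comp, new_comp)
        comp, sol = new_comp, new_sol
        path.append(sol["loglik"])
        if verbose:
            print(f"iter {it}: loglik={sol['loglik']:.6f} delta={delta:.3e}")
        # a small parameter change only signals convergence when the step was
        # not heavily damped by the line search
        if delta < tol and (used_scale is None or used_scale >= 0.5):
            converged = True
            break
        # stalled at the optimum (e.g., a component pinned at the PSD boundary
        # where the parameter change cannot fall below tol): no material
        # likelihood gain over the last several rounds despite AI steps
        if use_ai and it >= 12:
            recent = np.array(path[-12:])
            if recent.max() - recent.min() < 1e-6 * (1.0 + abs(recent[-1])):
                converged = True
                break
    if not converged:
        warnings.warn("REML did not converge within max_iter")
    fixed = pd.Series(sol["beta"], index=sys_.fixed_names)
    return RRMFit(
        components=comp,
        basis=basis,
        animal_ids=sys_.full_animal_ids,
        cow_ids=sys_.cow_ids,
        a_hat=sys_.expand_a(sol["a_hat"]),
        p_hat=sol["p_hat"],
        fixed_solutions=fixed,
        loglik=float(sol["loglik"]),
        n_iter=n_done,
        converged=converged,
        loglik_path=np.array(path),
    )


def _to_coords(comp: VarianceComponents) -> np.ndarray:
    """Unconstrained coordinates: lower-triangular factors and log residual."""
    k = comp.n_coef
    tril = np.tril_indices(k)
    return np.concatenate([
        _psd_cholesky(comp.G)[tril],
        _psd_cholesky(comp.P)[tril],
        [np.log(comp.sigma_e2)],
    ])


def _from_coords(x: np.ndarray, k: int) -> VarianceComponents:
    tril = np.tril_indices(k)
    nL = len(tril[0])
    LG = np.zeros((k, k))
    LP = np.zeros((k, k))
    LG[tril] = x[:nL]
    LP[tril] = x[nL : 2 * nL]
    G = LG @ LG.T
    P = LP @ LP.T
    G += 1e-10 * max(np.trace(G), 1e-6) * np.eye(k)
    P += 1e-10 * max(np.trace(P), 1e-6) * np.eye(k)
    return VarianceComponents(G, P, float(np.exp(x[-1])))


def _squarem_cycle(sys_: MMESystem, comp: VarianceComponents, sol):
    """One SQUAREM cycle: two EM steps plus a squared extrapolation in the
    Cholesky coordinates (monotone by construction: the extrapolated point is
    only taken when it beats the second EM step)."""
    k = comp.n_coef
    pieces = _trace_pieces(sys_, sol)
    em1 = _em_update(sys_, comp, sol, pieces)
    sol1 = sys_.solve(em1, want_inverse=True)
    em2 = _em_update(sys_, em1, sol1, _trace_pieces(sys_, sol1))
    sol2 = sys_.solve(em2, want_inverse=True)

    x0, x1, x2 = _to_coords(comp), _to_coords(em1), _to_coords(em2)
    r = x1 - x0
    v = (x2 - x1) - r
    nv = np.linalg.norm(v)
    best_comp, best_sol = em2, sol2
    if nv > 1e-14:
        alpha = -np.linalg.norm(r) / nv
        while alpha < -1.0:
            cand = _from_coords(x0 - 2 * alpha * r + alpha**2 * v, k)
            try:
                trial = sys_.solve(cand, want_inverse=True)
            except (np.linalg.LinAlgError, linalg.LinAlgError):
                trial = None
            if trial is not None and trial["loglik"] > best_sol["loglik"]:
                best_comp, best_sol = cand, trial
                break
            alpha = (alpha - 1.0) / 2.0  # back off toward plain EM
    return best_comp, best_sol


def _param_change(old: VarianceComponents, new: VarianceComponents) -> float:
    ov = np.concatenate([old.G.ravel(), old.P.ravel(), [old.sigma_e2]])
    nv = np.concatenate([new.G.ravel(), new.P.ravel(), [new.sigma_e2]])
    denom = np.maximum(np.abs(ov), 1e-8)
    return float(np.max(np.abs(nv - ov) / denom))


# ---------------------------------------------------------------------------
# sklearn-style estimator


class RandomRegressionModel(BaseEstimator):
    """Random-regression test-day model as a fit-shaped estimator.

    Parameters
    ----------
    basis_order : order of the Legendre regressions (field default 5; lower
        orders are useful for desk-scale work).
    fixed_factors : categorical record columns entering as fixed effects.
    tol, max_iter, use_ai : REML controls; see :func:`reml_fit`.

    After ``fit(records, pedigree=...)`` the instance exposes ``components_``,
    ``a_hat_``, ``p_hat_``, ``loglik_``, ``converged_`` and helpers
    ``heritability``, ``correlation``, ``ebv``.
    """

    def __init__(self, basis_order=5, dim_min=5, dim_max=305, normalized=True,
                 value_col="value", fixed_factors=DEFAULT_FIXED_FACTORS,
                 tol=1e-6, max_iter=500, use_ai=True, init=None):
        self.basis_order = basis_order
        self.dim_min = dim_min
        self.dim_max = dim_max
        self.normalized = normalized
        self.value_col = value_col
        self.fixed_factors = fixed_factors
        self.tol = tol
        self.max_iter = max_iter
        self.use_ai = use_ai
        self.init = init

    def fit(self, X, y=None, *, pedigree: Pedigree):
        """X: test-day record DataFrame with cow_id, dim, factor and value columns."""
        basis = LegendreBasis(order=self.basis_order, dim_min=self.dim_min,
                              dim_max=self.dim_max, normalized=self.normalized)
        fit = reml_fit(X, pedigree, basis, init=self.init,
                       value_col=self.value_col, factors=self.fixed_factors,
                       tol=self.tol, max_iter=self.max_iter, use_ai=self.use_ai)
        self.basis_ = basis
        self.fit_ = fit
        self.components_ = fit.components
        self.a_hat_ = fit.a_hat
        self.p_hat_ = fit.p_hat
        self.animal_ids_ = fit.animal_ids
        self.cow_ids_ = fit.cow_ids
        self.fixed_solutions_ = fit.fixed_solutions
        self.loglik_ = fit.loglik
        self.loglik_path_ = fit.loglik_path
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        return self

    def heritability(self, dims=DEFAULT_DIM_GRID):
        return heritability_curve(self.components_, self.basis_, dims)

    def correlation(self, dim1, dim2):
        return genetic_correlation(self.components_, self.basis_, dim1, dim2)

    def correlation_grid(self, dims=DEFAULT_DIM_GRID):
        return genetic_correlation_grid(self.components_, self.basis_, dims)

    def ebv(self, animal, dim):
        return ebv_at_dim(self.fit_, self.basis_, animal, dim)

    def ebv_table(self, dims=DEFAULT_DIM_GRID, animals=None):
        return ebv_table(self.fit_, dims, animals)
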