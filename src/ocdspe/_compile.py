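"""Symbolic vector fields compiled to vectorized numpy callables.

Every dynamical constraint used by the estimators (raw model dynamics,
data-controlled dynamics, estimation dynamics over states and momenta) is
represented as a :class:`CompiledField`: a list of sympy expressions in four
groups of symbols — path variables ``z``, static parameters ``theta``,
control paths ``u``, and exogenous data paths ``data`` — together with
exact Jacobians with respect to each differentiable group.  All callables
broadcast over time: a ``(Dz, N)`` path evaluates in a single call.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

__all__ = ["CompiledField"]


def _lambdify(args, exprs):
    return sp.lambdify(args, exprs, modules="numpy", cse=True)


def _stack_rows(rows, ncols):
    """Broadcast a flat list of scalars/arrays to a (len(rows), ncols) array."""
    out = np.empty((len(rows), ncols), dtype=float)
    for i, r in enumerate(rows):
        out[i] = r  # scalar entries (constant expressions) broadcast
    return out


class CompiledField:
    """A vector field f(z; theta, u, data) with exact Jacobians.

    Parameters
    ----------
    z_syms, theta_syms, u_syms, data_syms : sequences of sympy Symbols
        Path variables, static parameters, control paths and data paths.
    exprs : sequence of sympy expressions
        One expression per component of the field, length ``Dz``.
    """

    def __init__(self, z_syms, theta_syms, u_syms, data_syms, exprs):
        self.z_syms = list(z_syms)
        self.theta_syms = list(theta_syms)
        self.u_syms = list(u_syms)
        self.data_syms = list(data_syms)
        self.exprs = list(exprs)
        self.dim = len(self.exprs)
        if self.dim != len(self.z_syms):
            raise ValueError("field dimension must match number of path symbols")

        args = self.z_syms + self.theta_syms + self.u_syms + self.data_syms
        mat = sp.Matrix(self.exprs)
        self._f = _lambdify(args, self.exprs)
        self._jz = self._compile_jac(args, mat.jacobian(self.z_syms))
        self._jth = (
            self._compile_jac(args, mat.jacobian(self.theta_syms))
            if self.theta_syms
            else None
        )
        self._ju = (
            self._compile_jac(args, mat.jacobian(self.u_syms)) if self.u_syms else None
        )

    @staticmethod
    def _compile_jac(args, jac):
        """Split a Jacobian into a constant template plus lambdified
        non-constant entries (most entries of these fields are 0 or +/-1)."""
        rows, cols = jac.shape
        template = np.zeros((rows, cols))
        slots, exprs = [], []
        for i in range(rows):
            for j in range(cols):
                e = jac[i, j]
                if e.free_symbols:
                    slots.append((i, j))
                    exprs.append(e)
                else:
                    template[i, j] = float(e)
        fn = _lambdify(args, exprs) if exprs else None
        return template, slots, fn

    # -- evaluation helpers -------------------------------------------------
    def _args(self, z, theta, u, data):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        parts = list(z)
        if self.theta_syms:
            # scalar parameters broadcast; per-column arrays batch a scan
            parts += [
                v if np.ndim(v) else float(v)
                for v in (np.asarray(t, dtype=float) for t in np.atleast_1d(theta))
            ]
        if self.u_syms:
            parts += list(np.atleast_2d(np.asarray(u, dtype=float)))
        if self.data_syms:
            parts += list(np.atleast_2d(np.asarray(data, dtype=float)))
        return parts, z.shape[1]

    def f(self, z, theta=(), u=None, data=None):
        """Field values, shape ``(Dz, N)``."""
        parts, n = self._args(z, theta, u, data)
        return _stack_rows(self._f(*parts), n)

    def _jac(self, compiled, z, theta, u, data):
        template, slots, fn = compiled
        parts, n = self._args(z, theta, u, data)
        out = np.empty(template.shape + (n,), dtype=float)
        out[:] = template[:, :, None]
        if fn is not None:
            for (i, j), val in zip(slots, fn(*parts)):
                out[i, j] = val
        return out

    def jac_z(self, z, theta=(), u=None, data=None):
        """d f / d z, shape ``(Dz, Dz, N)``."""
        return self._jac(self._jz, z, theta, u, data)

    def jac_theta(self, z, theta=(), u=None, data=None):
        """d f / d theta, shape ``(Dz, P, N)``."""
        return self._jac(self._jth, z, theta, u, data)

    def jac_u(self, z, theta=(), u=None, data=None):
        """d f / d u, shape ``(Dz, Du, N)``."""
        return self._jac(self._ju, z, theta, u, data)
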