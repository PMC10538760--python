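"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports higher-order derivatives: every vector-Jacobian product is itself
built from primitive ops, so ``grad`` applied to the output of ``grad``
yields correct second derivatives. This is what the Wasserstein gradient
penalty needs — the penalty is a function of the discriminator's *input*
gradient, and training differentiates it again with respect to the
discriminator's parameters.

Only the small set of ops the package uses is implemented (dense linear
algebra, elementwise transcendentals, reductions, column gather/scatter).
Arrays follow numpy broadcasting; gradients of broadcast ops are summed
back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "tensor", "parameter", "grad",
    "add", "sub", "mul", "div", "neg", "matmul", "transpose", "power",
    "exp", "log", "tanh", "reshape", "sum_", "mean_",
    "gather_cols", "scatter_cols", "concat_cols",
    "leaky_relu", "elu", "logistic", "softplus", "row_norm", "linear",
]


class Tensor:
    """A node in the computation graph wrapping a numpy array.

    ``parents`` is a list of ``(parent, vjp)`` pairs where ``vjp`` maps the
    gradient at this node (a Tensor) to the gradient contribution at the
    parent (also a Tensor, so the backward pass is differentiable).
    """

    __slots__ = ("data", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.parents = tuple(parents)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, idx):
        # column gather only (used by discriminator cells)
        raise TypeError("use gather_cols for differentiable indexing")

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def tensor(data):
    """Wrap ``data`` as a constant (no gradient tracked into it)."""
    return Tensor(data)


def parameter(data):
    """Wrap ``data`` as a trainable leaf."""
    return Tensor(np.array(data, dtype=float), requires_grad=True)


# ---------------------------------------------------------------------
# broadcasting helper: reduce ``g`` back to ``shape``

def _unbroadcast(g, shape):
    if g.shape == shape:
        return g
    # sum over extra leading axes
    extra = g.ndim - len(shape)
    for _ in range(extra):
        g = sum_(g, axis=0)
    # sum over axes broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = sum_(g, axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------
# primitives

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    return Tensor(
        a.data + b.data,
        parents=[
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(g, b.shape)),
        ],
    )


def sub(a, b):
    a, b = _wrap(a), _wrap(b)
    return Tensor(
        a.data - b.data,
        parents=[
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(neg(g), b.shape)),
        ],
    )


def neg(a):
    a = _wrap(a)
    return Tensor(-a.data, parents=[(a, lambda g: Tensor(np.zeros(())) - g)])


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    return Tensor(
        a.data * b.data,
        parents=[
            (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
            (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
        ],
    )


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    return mul(a, power(b, -1.0))


def power(a, p):
    a = _wrap(a)
    p = float(p)
    out = Tensor(a.data ** p)
    out.parents = ((a, lambda g: _unbroadcast(mul(g, mul(Tensor(p), power(a, p - 1.0))), a.shape)),)
    out.requires_grad = a.requires_grad
    return out


def exp(a):
    a = _wrap(a)
    out = Tensor(np.exp(a.data))
    out.parents = ((a, lambda g: mul(g, out)),)
    out.requires_grad = a.requires_grad
    return out


def log(a):
    a = _wrap(a)
    return Tensor(np.log(a.data), parents=[(a, lambda g: div(g, a))])


def tanh(a):
    a = _wrap(a)
    out = Tensor(np.tanh(a.data))
    out.parents = ((a, lambda g: mul(g, sub(Tensor(1.0), mul(out, out)))),)
    out.requires_grad = a.requires_grad
    return out


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    return Tensor(
        a.data @ b.data,
        parents=[
            (a, lambda g: matmul(g, transpose(b))),
            (b, lambda g: matmul(transpose(a), g)),
        ],
    )


def transpose(a):
    a = _wrap(a)
    return Tensor(a.data.T, parents=[(a, lambda g: transpose(g))])


def reshape(a, shape):
    a = _wrap(a)
    old = a.shape
    return Tensor(a.data.reshape(shape), parents=[(a, lambda g: reshape(g, old))])


def sum_(a, axis=None, keepdims=False):
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return mul(g, Tensor(np.ones(a.shape)))
        gk = g
        if not keepdims:
            kshape = list(a.shape)
            for ax in (axis,) if isinstance(axis, int) else axis:
                kshape[ax] = 1
            gk = reshape(g, tuple(kshape))
        return mul(gk, Tensor(np.ones(a.shape)))

    return Tensor(out_data, parents=[(a, vjp)])


def mean_(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in ((axis,) if isinstance(axis, int) else axis)]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def concat_cols(a, b):
    """Join two 2-D tensors along columns; differentiable."""
    a, b = _wrap(a), _wrap(b)
    da = a.shape[1]
    db = b.shape[1]
    return Tensor(
        np.concatenate([a.data, b.data], axis=1),
        parents=[
            (a, lambda g: gather_cols(g, np.arange(da))),
            (b, lambda g: gather_cols(g, np.arange(da, da + db))),
        ],
    )


def gather_cols(a, idx):
    """Select columns ``idx`` of a 2-D tensor; differentiable."""
    a = _wrap(a)
    idx = np.asarray(idx, dtype=int)
    width = a.shape[1]
    return Tensor(
        a.data[:, idx],
        parents=[(a, lambda g: scatter_cols(g, idx, width))],
    )


def scatter_cols(g, idx, width):
    """Adjoint of gather_cols: place columns of ``g`` at ``idx`` in a
    zero matrix of ``width`` columns (duplicate indices accumulate)."""
    g = _wrap(g)
    idx = np.asarray(idx, dtype=int)
    out = np.zeros((g.shape[0], width))
    np.add.at(out, (slice(None), idx), g.data)
    return Tensor(out, parents=[(g, lambda h: gather_cols(h, idx))])


# ---------------------------------------------------------------------
# composites (built from primitives, so double backprop works through them)

def leaky_relu(x, negative_slope=0.2):
    x = _wrap(x)
    mask = Tensor((x.data > 0).astype(float))
    return add(mul(mask, x), mul(Tensor(negative_slope), mul(sub(Tensor(1.0), mask), x)))


def elu(x):
    x = _wrap(x)
    mask = Tensor((x.data > 0).astype(float))
    return add(mul(mask, x), mul(sub(Tensor(1.0), mask), sub(exp(mul(sub(Tensor(1.0), mask), x)), Tensor(1.0))))


def logistic(x):
    x = _wrap(x)
    return div(Tensor(1.0), add(Tensor(1.0), exp(neg(x))))


def softplus(x):
    x = _wrap(x)
    return log(add(Tensor(1.0), exp(x)))


def row_norm(x, eps=1e-12):
    """Euclidean norm of each row of a 2-D tensor."""
    return power(add(sum_(mul(x, x), axis=1), Tensor(eps)), 0.5)


def linear(x, w, b):
    """Affine map ``x @ w + b`` for a (batch, d_in) input."""
    return add(matmul(x, w), b)


# ---------------------------------------------------------------------
# backward pass

def _topo(root):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p, _ in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output, inputs, grad_output=None):
    """Gradients of ``output`` with respect to each tensor in ``inputs``.

    ``grad_output`` seeds the backward pass (defaults to ones). The
    returned gradients are Tensors whose graphs extend the forward graph,
    so they can be differentiated again.
    """
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    seed = grad_output if grad_output is not None else Tensor(np.ones(output.shape))
    grads = {id(output): seed}
    for node in reversed(_topo(output)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in node.parents:
            if not parent.requires_grad:
                continue
            contrib = vjp(g)
            if id(parent) in grads:
                grads[id(parent)] = add(grads[id(parent)], contrib)
            else:
                grads[id(parent)] = contrib
        # keep gradient available for requested inputs
        if any(node is t for t in inputs):
            grads[id(node)] = g
    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros(t.shape))
        out.append(g)
    return out[0] if single else out
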