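"""Reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the network and the meta-learner are built on.
``Tensor`` wraps a float64 numpy array and records the operations applied to
it; :func:`grad` walks the recorded graph backwards. Every backward rule is
itself written in terms of ``Tensor`` primitives, so gradients are ordinary
graph nodes and can be differentiated again — which is what second-order
meta-learning (gradient through the inner adaptation step) requires.

Only the primitives the package needs are provided: elementwise arithmetic,
matmul, reductions, shape ops, padding/cropping of image tensors, and a
gather/scatter pair used to express convolution as im2col + matmul.
"""

from __future__ import annotations

from contextlib import contextmanager, nullcontext

import numpy as np

__all__ = [
    "Tensor", "no_grad", "grad", "as_tensor",
    "add", "mul", "matmul", "einsum2", "exp", "log", "relu", "sigmoid",
    "sum_", "max_", "mean_", "reshape", "transpose", "broadcast_to",
    "pad2d", "crop2d", "slice_hw", "pad_hw", "take_cols", "scatter_cols",
    "set_default_dtype", "default_dtype",
]

_GRAD_ENABLED = True
_DTYPE = np.float64


def set_default_dtype(dtype):
    """Set the array dtype new tensors are cast to (float64 or float32).

    float64 is the default and what the exactness tests assume; float32
    halves memory traffic and roughly doubles training throughput.
    """
    global _DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float64), np.dtype(np.float32)):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = np.dtype(dtype).type


@contextmanager
def default_dtype(dtype):
    global _DTYPE
    prev = _DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        _DTYPE = prev


class no_grad:
    """Context manager disabling graph recording."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._vjp = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return mul(self, as_tensor(-1.0))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, pow_(as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), pow_(self, -1.0))

    def __pow__(self, p):
        return pow_(self, float(p))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp):
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._vjp = vjp
    return out


def _sum_to(g, shape):
    """Reduce a (possibly broadcast) gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = sum_(g, axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return g


# -- elementwise -------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data + b.data, (a, b),
                 lambda g: (_sum_to(g, a.shape), _sum_to(g, b.shape)))


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(a.data * b.data, (a, b),
                 lambda g: (_sum_to(mul(g, b), a.shape), _sum_to(mul(g, a), b.shape)))


def pow_(a, p):
    a = as_tensor(a)
    p = float(p)
    return _node(a.data ** p, (a,),
                 lambda g: (mul(g, mul(as_tensor(p), pow_(a, p - 1.0))),))


def exp(a):
    a = as_tensor(a)
    out = _node(np.exp(a.data), (a,), None)
    out._vjp = (lambda g: (mul(g, out),)) if out.requires_grad else None
    return out


def log(a):
    a = as_tensor(a)
    return _node(np.log(a.data), (a,), lambda g: (mul(g, pow_(a, -1.0)),))


def relu(a):
    a = as_tensor(a)
    mask = Tensor(a.data > 0)
    return _node(a.data * mask.data, (a,), lambda g: (mul(g, mask),))


def sigmoid(a):
    a = as_tensor(a)
    out_data = 0.5 * (1.0 + np.tanh(0.5 * a.data))  # overflow-free logistic
    out = _node(out_data, (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, mul(out, add(as_tensor(1.0), -out))),)
    return out


# -- linear algebra ----------------------------------------------------

def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands")

    def vjp(g):
        # skip the adjoint GEMM of a constant operand (e.g. the im2col patch
        # matrix of a constant input) — it would be discarded anyway
        return (matmul(g, transpose(b, (1, 0))) if a.requires_grad else None,
                matmul(transpose(a, (1, 0)), g) if b.requires_grad else None)

    return _node(a.data @ b.data, (a, b), vjp)


def einsum2(spec, a, b):
    """Two-operand einsum without traces or diagonals.

    Every index must appear in exactly two of the three terms; then the
    adjoints are einsums with the terms swapped, which keeps this primitive
    differentiable to any order. Contractions here compile to GEMM, which is
    what makes the im2col convolution fast.
    """
    a, b = as_tensor(a), as_tensor(b)
    ins, so = spec.split("->")
    sa, sb = ins.split(",")
    ga_spec = f"{so},{sb}->{sa}"
    gb_spec = f"{so},{sa}->{sb}"

    def vjp(g):
        return (einsum2(ga_spec, g, b) if a.requires_grad else None,
                einsum2(gb_spec, g, a) if b.requires_grad else None)

    return _node(np.einsum(spec, a.data, b.data, optimize=True), (a, b), vjp)


# -- reductions --------------------------------------------------------

def _keepdims_shape(shape, axis):
    if axis is None:
        return (1,) * len(shape)
    axes = axis if isinstance(axis, tuple) else (axis,)
    axes = tuple(a % len(shape) for a in axes)
    return tuple(1 if i in axes else s for i, s in enumerate(shape))


def sum_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    kshape = _keepdims_shape(a.shape, axis)

    def vjp(g):
        return (broadcast_to(reshape(g, kshape), a.shape),)

    return _node(np.sum(a.data, axis=axis, keepdims=keepdims), (a,), vjp)


def mean_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(a, axis=axis, keepdims=keepdims), as_tensor(1.0 / float(n)))


def max_(a, axis, keepdims=False):
    """Max along one integer axis. Subgradient: all mass on the first argmax."""
    a = as_tensor(a)
    am = np.argmax(a.data, axis=axis)
    onehot = np.zeros_like(a.data)
    np.put_along_axis(onehot, np.expand_dims(am, axis), 1.0, axis)
    mask = Tensor(onehot)
    kshape = _keepdims_shape(a.shape, axis)

    def vjp(g):
        return (mul(broadcast_to(reshape(g, kshape), a.shape), mask),)

    return _node(np.max(a.data, axis=axis, keepdims=keepdims), (a,), vjp)


# -- shape -------------------------------------------------------------

def reshape(a, shape):
    a = as_tensor(a)
    old = a.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (reshape(g, old),))


def transpose(a, axes):
    a = as_tensor(a)
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def broadcast_to(a, shape):
    a = as_tensor(a)
    old = a.shape
    return _node(np.broadcast_to(a.data, shape).copy(), (a,),
                 lambda g: (reshape(_sum_to(g, (1,) * (len(shape) - len(old)) + tuple(old)), old),))


def slice_hw(a, r0, r1, c0, c1):
    """Slice the last two axes: ``a[..., r0:r1, c0:c1]``."""
    a = as_tensor(a)
    oh, ow = a.shape[-2], a.shape[-1]

    def vjp(g):
        return (pad_hw(g, oh, ow, r0, c0),)

    return _node(a.data[..., r0:r1, c0:c1], (a,), vjp)


def pad_hw(a, out_h, out_w, r0, c0):
    """Embed ``a`` into zeros of spatial size ``out_h×out_w`` at offset (r0, c0)."""
    a = as_tensor(a)
    h, w = a.shape[-2], a.shape[-1]

    def forward(d):
        out = np.zeros(d.shape[:-2] + (out_h, out_w))
        out[..., r0:r0 + h, c0:c0 + w] = d
        return out

    def vjp(g):
        return (slice_hw(g, r0, r0 + h, c0, c0 + w),)

    return _node(forward(a.data), (a,), vjp)


def pad2d(a, p):
    """Zero-pad the last two axes by ``p`` on each side."""
    a = as_tensor(a)
    return pad_hw(a, a.shape[-2] + 2 * p, a.shape[-1] + 2 * p, p, p)


def crop2d(a, h, w):
    """Take the top-left ``h×w`` corner of the last two axes."""
    return slice_hw(as_tensor(a), 0, h, 0, w)


# -- gather / scatter (im2col support) ---------------------------------

def take_cols(a, idx, smat=None):
    """``out[i, j] = a[i, idx[j]]`` for a 2-D tensor and constant index.

    ``smat`` optionally carries a precomputed sparse scatter matrix for the
    adjoint (see :func:`scatter_matrix`); without it the adjoint falls back
    to ``np.add.at``, which is much slower for large indices.
    """
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    n = a.shape[1]
    return _node(a.data[:, idx], (a,), lambda g: (scatter_cols(g, idx, n, smat),))


def scatter_matrix(idx, n):
    """CSR matrix S with S[j, idx[j]] = 1, so scatter-add is ``g @ S``."""
    from scipy import sparse
    m = len(idx)
    # float32 ones are exact and avoid forcing float64 in float32 mode
    return sparse.csr_matrix((np.ones(m, dtype=np.float32), (np.arange(m), idx)),
                             shape=(m, n))


def scatter_cols(a, idx, n, smat=None):
    """Adjoint of :func:`take_cols`: scatter-add columns into width ``n``."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def forward(data):
        if smat is not None:
            return np.asarray(data @ smat)
        tmp = np.zeros((n, data.shape[0]))
        np.add.at(tmp, idx, data.T)
        return tmp.T.astype(data.dtype, copy=False)

    return _node(forward(a.data), (a,), lambda g: (take_cols(g, idx, smat),))


# -- backward pass -----------------------------------------------------

def grad(output, inputs, create_graph=False, grad_output=None):
    """Gradients of a scalar ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned gradients are themselves graph
    nodes and support further differentiation.
    """
    if grad_output is None:
        if output.size != 1:
            raise ValueError("grad() requires a scalar output")
        grad_output = Tensor(np.ones_like(output.data))

    # topological order (iterative post-order over the requires_grad subgraph)
    topo, visited, stack = [], set(), [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))

    grads = {id(output): grad_output}
    ctx = nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = grads.get(id(node))
            if g is None or node._vjp is None:
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                acc = grads.get(id(parent))
                grads[id(parent)] = pg if acc is None else add(acc, pg)

    return [grads.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs]
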