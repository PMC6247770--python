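"""Optional numba acceleration.

The integration kernels are plain scalar loops; when numba is present they
are JIT-compiled, otherwise the pure-Python versions run (slower but exact).
"""

from __future__ import annotations

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


__all__ = ["njit"]
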