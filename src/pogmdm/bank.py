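"""Convolutional filter banks with circular boundary handling.

A bank holds ``o`` linear filters, given either as small spatial kernels
(realized on the image grid by FFT-based circular convolution) or directly as
real, even-symmetric full-grid spectra (used for shearlets).  The spectral
magnitude of each filter is cached because it drives the theory-derived time
conditioning ``sigma_k^2(t) = sigma_0^2 + nu_k^2 * 2t``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FilterBank", "project_zero_mean", "nu_from_filter", "embed_kernel"]


def project_zero_mean(f: np.ndarray) -> np.ndarray:
    """Subtract the mean of a kernel; idempotent, shape preserving."""
    f = np.asarray(f, dtype=float)
    return f - f.mean()


def embed_kernel(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad a small kernel into a full grid, centered at the origin.

    The kernel's center tap lands on index (0, 0) with circular wrap so that
    the resulting spectrum has (close to) linear phase removed.
    """
    kernel = np.atleast_2d(np.asarray(kernel, dtype=float))
    kh, kw = kernel.shape
    h, w = shape
    if kh > h or kw > w:
        raise ValueError("kernel does not fit into the grid")
    grid = np.zeros(shape)
    grid[:kh, :kw] = kernel
    return np.roll(grid, (-(kh // 2), -(kw // 2)), axis=(0, 1))


def nu_from_filter(kernel: np.ndarray, shape: tuple[int, int],
                   heuristic: str = "max") -> float:
    """Diffusion-scaling heuristic ``nu^2`` from a kernel's spectrum.

    ``nu^2`` is the maximum (default) or the mean of the magnitude spectrum of
    the zero-padded kernel on the full grid.  The two choices behave almost
    identically in practice.
    """
    spec = np.abs(np.fft.fft2(embed_kernel(kernel, shape)))
    if heuristic == "max":
        return float(spec.max())
    if heuristic == "mean":
        return float(spec.mean())
    raise ValueError(f"unknown heuristic {heuristic!r}")


class FilterBank:
    """Bank of ``o`` filters on a fixed grid with circular boundaries.

    Parameters
    ----------
    kernels:
        Optional list of small real 2D kernels.
    spectra:
        Optional array ``(o, h, w)`` of real full-grid transfer functions
        (used for shearlet banks).  Exactly one of ``kernels``/``spectra``
        must be given.
    grid_shape:
        Image grid the bank operates on.
    zero_mean:
        If True, kernels are projected to zero mean on construction and by
        :meth:`project`.
    learnable:
        Whether the filter parameters count as learnable (for bookkeeping).
    n_filter_params:
        Override for the learnable filter parameter count (shearlet banks are
        parameterized by ``h1`` and ``P``, not by their ``o`` spectra).
    """

    def __init__(self, kernels=None, spectra=None, grid_shape=None,
                 zero_mean: bool = False, learnable: bool = True,
                 n_filter_params: int | None = None,
                 nu_heuristic: str = "max"):
        if (kernels is None) == (spectra is None):
            raise ValueError("give exactly one of kernels or spectra")
        if grid_shape is None:
            if spectra is None:
                raise ValueError("grid_shape is required with spatial kernels")
            grid_shape = np.asarray(spectra).shape[1:]
        self.grid_shape = tuple(int(n) for n in grid_shape)
        self.zero_mean = bool(zero_mean)
        self.learnable = bool(learnable)
        self.nu_heuristic = nu_heuristic
        if kernels is not None:
            self.kernels = [np.atleast_2d(np.asarray(k, dtype=float)).copy()
                            for k in kernels]
            if self.zero_mean:
                self.kernels = [project_zero_mean(k) for k in self.kernels]
            self._spectra = None
        else:
            self.kernels = None
            self._spectra = np.asarray(spectra, dtype=float).copy()
        self._n_filter_params = n_filter_params
        self._refresh_cache()

    # -- cache ----------------------------------------------------------

    def _refresh_cache(self) -> None:
        if self.kernels is not None:
            self._transfer = np.stack(
                [np.fft.fft2(embed_kernel(k, self.grid_shape))
                 for k in self.kernels])
        else:
            self._transfer = self._spectra.astype(complex)
        self.spectral_magnitude = np.abs(self._transfer)

    def project(self) -> None:
        """Apply the bank's constraints (zero mean) and refresh caches."""
        if self.kernels is not None and self.zero_mean:
            self.kernels = [project_zero_mean(k) for k in self.kernels]
        self._refresh_cache()

    # -- properties -----------------------------------------------------

    @property
    def o(self) -> int:
        return self._transfer.shape[0]

    @property
    def n_filter_params(self) -> int:
        if not self.learnable:
            return 0
        if self._n_filter_params is not None:
            return self._n_filter_params
        return int(sum(k.size for k in self.kernels))

    def nu_sq(self) -> np.ndarray:
        """Per-filter diffusion scaling ``nu_k^2`` from the cached spectra."""
        if self.nu_heuristic == "max":
            return self.spectral_magnitude.max(axis=(1, 2))
        return self.spectral_magnitude.mean(axis=(1, 2))

    # -- application ----------------------------------------------------

    def apply(self, x: np.ndarray) -> np.ndarray:
        """All filter responses ``K_k x``; returns shape ``(o, h, w)``."""
        if x.shape != self.grid_shape:
            raise ValueError(f"image shape {x.shape} != grid {self.grid_shape}")
        X = np.fft.fft2(x)
        return np.real(np.fft.ifft2(self._transfer * X[None]))

    def apply_adjoint(self, u: np.ndarray) -> np.ndarray:
        """``sum_k K_k^T u_k`` for a stack of response fields ``(o, h, w)``."""
        U = np.fft.fft2(u, axes=(-2, -1))
        out = np.sum(np.conj(self._transfer) * U, axis=0)
        return np.real(np.fft.ifft2(out))

    @classmethod
    def identity(cls, grid_shape) -> "FilterBank":
        """Single delta filter: responses equal the image (nu^2 = 1)."""
        return cls(kernels=[np.array([[1.0]])], grid_shape=grid_shape,
                   learnable=False)

    @classmethod
    def random_learnable(cls, o: int, r: int, grid_shape, rng) -> "FilterBank":
        """Fully learnable zero-mean r x r filters, N(0, 1/(o r^2)) init."""
        ks = [rng.normal(0.0, 1.0 / np.sqrt(o * r * r), size=(r, r))
              for _ in range(o)]
        return cls(kernels=ks, grid_shape=grid_shape, zero_mean=True)
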