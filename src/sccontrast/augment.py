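"""Masking augmentation: two independently masked views of the expression matrix.

Each view zeroes a Bernoulli(mask_rate) subset of entries and, by default,
rescales survivors by 1/(1-mask_rate) (inverted-dropout semantics) so the
expected value of every entry is preserved.  The cell graph is never
perturbed by augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AugmentedViews", "make_views"]


@dataclass
class AugmentedViews:
    view1: np.ndarray
    view2: np.ndarray
    mask_rate: float
    seed: int


def _one_view(x: np.ndarray, mask_rate: float, rng: np.random.Generator,
              rescale: bool) -> np.ndarray:
    if mask_rate == 0.0:
        return x.copy()
    keep = rng.random(x.shape) >= mask_rate
    out = x * keep
    if rescale:
        out /= 1.0 - mask_rate
    return out


def make_views(
    x: np.ndarray,
    mask_rate: float = 0.5,
    seed: int = 0,
    epoch: int = 0,
    rescale: bool = True,
) -> AugmentedViews:
    """Draw two independent masked views of `x`.

    Deterministic in (seed, epoch): the mask stream is keyed on both so
    masks are reproducible yet differ across epochs, and the two views
    always use independent streams.
    """
    if not 0.0 <= mask_rate < 1.0:
        raise ValueError(f"mask_rate must be in [0, 1), got {mask_rate}")
    x = np.asarray(x, dtype=np.float64)
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                spawn_key=(int(epoch),))
    rng1, rng2 = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(2))
    return AugmentedViews(
        view1=_one_view(x, mask_rate, rng1, rescale),
        view2=_one_view(x, mask_rate, rng2, rescale),
        mask_rate=mask_rate,
        seed=int(seed),
    )
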