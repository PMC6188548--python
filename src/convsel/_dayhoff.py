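"""Dayhoff (PAM) amino-acid replacement model constants.

Exchangeabilities are the classic Dayhoff, Schwartz & Orcutt (1978) values
in the form distributed with standard phylogenetics software (lower
triangle of the symmetric exchangeability matrix, arbitrary scale) together
with the accompanying equilibrium amino-acid frequencies.  Residue order of
the raw tables is ARNDCQEGHILKMFPSTWYV; accessors below re-index to this
package's alphabetical amino-acid order.
"""

from __future__ import annotations

import numpy as np

from .genetics import AA_INDEX, N_AA

_DAYHOFF_ORDER = "ARNDCQEGHILKMFPSTWYV"

# fmt: off
_DAYHOFF_LOWER = [
    27, 98, 120, 36, 89, 198, 240, 23, 65, 41, 26, 72, 18, 250, 409, 371,
    0, 24, 208, 32, 0, 23, 246, 1, 9, 240, 64, 15, 464, 90, 14, 103, 154,
    26, 201, 8, 24, 905, 0, 103, 148, 139, 535, 77, 34, 318, 1, 14, 42,
    495, 229, 23, 95, 15, 0, 134, 1153, 125, 86, 24, 0, 71, 0, 0, 13, 95,
    66, 0, 0, 18, 0, 0, 11, 28, 44, 0, 0, 0, 0, 19, 161, 16, 0, 96, 49,
    716, 28, 606, 18, 73, 153, 114, 0, 153, 56, 53, 0, 0, 35, 81, 43, 61,
    11, 83, 30, 0, 51, 79, 34, 0, 22, 37, 10, 0, 7, 27, 17, 15, 34, 234,
    30, 0, 0, 54, 7, 44, 26, 0, 48, 94, 35, 22, 27, 127, 44, 257, 46, 336,
    196, 12, 24, 192, 0, 37, 889, 18, 527, 157, 32, 17, 33, 46, 28, 175,
    243, 0, 33, 96, 136, 0, 13, 10, 92, 17, 62, 104, 0, 0, 258, 11, 46,
    13, 76, 698, 12, 245, 78, 0, 0, 48, 550, 75, 34, 30, 0, 42, 157, 61,
    0, 28,
]

_DAYHOFF_FREQS = [
    0.087126912873087131, 0.040903959096040908, 0.040431959568040438,
    0.046871953128046873, 0.033473966526033475, 0.038254961745038257,
    0.049529950470049530, 0.088611911388088618, 0.033617966382033626,
    0.036885963114036892, 0.085356914643085369, 0.080481919518080480,
    0.014752985247014754, 0.039771960228039777, 0.050679949320050689,
    0.069576930423069588, 0.058541941458058543, 0.010493989506010494,
    0.029915970084029919, 0.064717935282064723,
]
# fmt: on


def dayhoff_exchangeabilities() -> np.ndarray:
    """Symmetric 20x20 exchangeability matrix in alphabetical residue order."""
    s = np.zeros((N_AA, N_AA))
    k = 0
    for i in range(1, N_AA):
        for j in range(i):
            s[i, j] = s[j, i] = _DAYHOFF_LOWER[k]
            k += 1
    perm = np.array([AA_INDEX[a] for a in _DAYHOFF_ORDER])
    out = np.zeros_like(s)
    out[np.ix_(perm, perm)] = s
    return out


def dayhoff_frequencies() -> np.ndarray:
    """Dayhoff equilibrium frequencies in alphabetical residue order."""
    out = np.zeros(N_AA)
    for a, f in zip(_DAYHOFF_ORDER, _DAYHOFF_FREQS):
        out[AA_INDEX[a]] = f
    out /= out.sum()
    return out
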