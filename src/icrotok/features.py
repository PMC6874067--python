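"""Composition/position feature operators and the 194-d feature vector.

The descriptor of one peptide window concatenates, in this fixed order:

======================  ======  =======================================
segment                 length  content
======================  ======  =======================================
``seq_moments``             30  raw ‖ central ‖ Hahn moments of the
                                row-major square layout of the SVV
``prim_moments``            30  same three families on the 20×20 PRIM
``rprim_moments``           30  same on the RPRIM
``fv``                      20  residue frequency vector
``aapiv``                   20  accumulative absolute position
                                incidence vector (forward)
``raapiv``                  20  reverse AAPIV
``svv``                     41  the raw site vicinity vector
``svv_stats``                3  mean, variance, skewness of the SVV
======================  ======  =======================================

Total: 194 values per window (flank ξ = 20).  Padding positions
(code 0) are excluded from every composition and position accumulator;
they remain visible only in the ``svv`` segment itself.

Positions are numbered 1..L over the window in AAPIV/PRIM accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .moments import moment_block, to_square_matrix
from .windows import PeptideWindow, encode_svv

N_RESIDUES = 20

#: Version tag for the 194-feature layout; serialized with trained
#: models so a feature-order mismatch is an error, never silent.
LAYOUT_VERSION = "icrotok-194-v1"


def _segment_layout(window_length: int) -> dict[str, tuple[int, int]]:
    """segment name -> (offset, length), covering [0, total) without gaps."""
    lengths = [
        ("seq_moments", 30),
        ("prim_moments", 30),
        ("rprim_moments", 30),
        ("fv", N_RESIDUES),
        ("aapiv", N_RESIDUES),
        ("raapiv", N_RESIDUES),
        ("svv", window_length),
        ("svv_stats", 3),
    ]
    layout, offset = {}, 0
    for name, length in lengths:
        layout[name] = (offset, length)
        offset += length
    return layout

#: Layout for the standard 41-residue window (ξ = 20): 194 features.
FEATURE_LAYOUT = _segment_layout(41)
N_FEATURES = 194


def feature_names(window_length: int = 41) -> list[str]:
    """Column names, one per feature, ``<segment>_<index>``."""
    names = []
    for segment, (_, length) in _segment_layout(window_length).items():
        names.extend(f"{segment}_{i}" for i in range(length))
    return names


def frequency_vector(seq: np.ndarray) -> np.ndarray:
    """Occurrence count of each residue (alphabetical rank order).

    ``f[i-1]`` is the number of positions carrying code ``i``; padding
    (code 0) is not counted, so ``f.sum()`` equals the number of
    non-padding positions.
    """
    seq = np.asarray(seq, dtype=int)
    return np.bincount(seq, minlength=N_RESIDUES + 1)[1:].astype(float)


def aapiv(seq: np.ndarray) -> np.ndarray:
    """Accumulative absolute position incidence vector.

    ``mu[i-1]`` is the sum of the 1-based window positions at which
    residue code ``i`` occurs; padding positions contribute nothing.
    """
    seq = np.asarray(seq, dtype=int)
    positions = np.arange(1, seq.size + 1)
    mu = np.zeros(N_RESIDUES)
    np.add.at(mu, seq[seq > 0] - 1, positions[seq > 0])
    return mu


def raapiv(seq: np.ndarray) -> np.ndarray:
    """Reverse AAPIV: the AAPIV of the reversed sequence."""
    return aapiv(np.asarray(seq)[::-1])


def prim(seq: np.ndarray) -> np.ndarray:
    """Position-relative incidence matrix (20×20).

    ``H[i-1, j-1]`` accumulates, over every occurrence of residue ``j``
    at a position ``p`` strictly after the first occurrence of residue
    ``i``, the relative offset ``p − first(i)`` (positions 1-based).
    Rows for absent residues are zero; padding is skipped entirely.
    """
    seq = np.asarray(seq, dtype=int)
    H = np.zeros((N_RESIDUES, N_RESIDUES))
    firsts: dict[int, int] = {}
    for pos0, code in enumerate(seq):
        if code > 0 and code not in firsts:
            firsts[code] = pos0 + 1
    for i, first_i in firsts.items():
        for pos0, j in enumerate(seq):
            p = pos0 + 1
            if j > 0 and p > first_i:
                H[i - 1, j - 1] += p - first_i
    return H


def rprim(seq: np.ndarray) -> np.ndarray:
    """Reverse PRIM: the PRIM of the reversed sequence."""
    return prim(np.asarray(seq)[::-1])


def _svv_stats(seq: np.ndarray) -> np.ndarray:
    """Mean, population variance and (biased) skewness of the SVV.

    A constant vector (e.g. an all-padding stress window) has undefined
    skewness; it is reported as 0.
    """
    seq = np.asarray(seq, dtype=float)
    var = float(np.var(seq))
    skew = float(stats.skew(seq)) if var > 0 else 0.0
    return np.array([float(np.mean(seq)), var, skew])


def assemble_feature_vector(window: PeptideWindow | str | np.ndarray) -> np.ndarray:
    """Build the full per-window descriptor (194 values at ξ = 20).

    Accepts a :class:`~icrotok.windows.PeptideWindow`, a raw residue
    string, or an already-encoded SVV.  Requires a window long enough
    (L ≥ 10) that its square layout supports the degree-3 Hahn basis.
    """
    if isinstance(window, (PeptideWindow, str)):
        seq = encode_svv(window)
    else:
        seq = np.asarray(window, dtype=int)
    parts = [
        moment_block(to_square_matrix(seq)),
        moment_block(prim(seq)),
        moment_block(rprim(seq)),
        frequency_vector(seq),
        aapiv(seq),
        raapiv(seq),
        seq.astype(float),
        _svv_stats(seq),
    ]
    vec = np.concatenate(parts)
    expected = sum(length for _, length in _segment_layout(seq.size).values())
    assert vec.size == expected  # layout covers the vector exactly
    return vec


def feature_segment(vec: np.ndarray, segment: str, window_length: int = 41) -> np.ndarray:
    """Slice one named segment out of an assembled feature vector."""
    offset, length = _segment_layout(window_length)[segment]
    return np.asarray(vec)[offset : offset + length]


@dataclass
class _FeaturizerState:
    window_length: int
    layout: dict[str, tuple[int, int]]


class PeptideFeaturizer(TransformerMixin, BaseEstimator):
    """Transform peptide windows into the 194-d descriptor matrix.

    A stateless scikit-learn transformer: ``fit`` only records the
    window length (inferred from the first sample when not given) so
    that ``transform`` can refuse inconsistent inputs.

    Parameters
    ----------
    window_length : int or None
        Expected window length; inferred at ``fit`` when None.

    Attributes
    ----------
    window_length_ : int
        Length accepted by ``transform``.
    n_features_out_ : int
        Dimensionality of the output (194 for 41-mers).
    layout_version_ : str
        Identifier of the feature ordering, stored with trained models.
    """

    def __init__(self, window_length: int | None = None):
        self.window_length = window_length

    def fit(self, X, y=None):
        first = X[0] if len(X) else None
        if self.window_length is not None:
            length = self.window_length
        elif first is None:
            raise ValueError("cannot infer window length from empty input")
        else:
            length = len(first)
        self.window_length_ = int(length)
        self.layout_ = _segment_layout(self.window_length_)
        self.n_features_out_ = sum(l for _, l in self.layout_.values())
        self.layout_version_ = LAYOUT_VERSION
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "window_length_")
        rows = []
        for sample in X:
            if len(sample) != self.window_length_:
                raise ValueError(
                    f"window length {len(sample)} != fitted "
                    f"{self.window_length_}"
                )
            rows.append(assemble_feature_vector(sample))
        return np.vstack(rows) if rows else np.empty((0, self.n_features_out_))

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "window_length_")
        return np.asarray(feature_names(self.window_length_), dtype=object)


def featurize(windows, window_length: int | None = None) -> np.ndarray:
    """Functional wrapper: windows (or strings) -> (n, 194) matrix."""
    return PeptideFeaturizer(window_length).fit_transform(list(windows))
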