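"""Marker panels: allele frequencies in the native and exogenous populations.

Four named schemes are supported, differing in how informative the markers
are about allele origin:

====================  ========  ==============================  ==============================
scheme                alleles   native frequencies              exogenous frequencies
====================  ========  ==============================  ==============================
diagnostic            2         (1, 0)                          (0, 1)
diagnostic_like       2         (0.80, 0.20)                    (0.20, 0.80)
extra_diagnostic_like 2         (f, 1-f), f in {0.7..0.99}      (0.5, 0.5)
non_diagnostic        4         (0.80, 0.07, 0.06, 0.07)        (0.07, 0.80, 0.06, 0.07)
====================  ========  ==============================  ==============================

Diagnostic markers carry private alleles (every native founder is
homozygous for allele 1, every exogenous founder for allele 2), so allele
origin is read off without error.  Under the other schemes allele 1 is
merely *more common* in natives; count-based management that treats it as
diagnostic will sometimes be wrong, which is exactly the misidentification
risk the simulator quantifies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MarkerPanel", "make_panel", "draw_founder_marker_genotype", "SCHEMES"]

SCHEMES = ("diagnostic", "diagnostic_like", "extra_diagnostic_like", "non_diagnostic")

_EXTRA_ALLOWED_F = (0.7, 0.8, 0.9, 0.95, 0.99)


@dataclass(frozen=True)
class MarkerPanel:
    """A set of M markers with per-population base allele frequencies.

    ``native_freqs`` and ``exogenous_freqs`` are ``(M, A)`` arrays; allele
    labels are shared across the two populations.  ``native_allele_index``
    designates, per marker, the allele treated as "native" by count-based
    management (the most frequent allele in the native population).
    """

    scheme: str
    M: int
    alleles_per_marker: int
    native_freqs: np.ndarray
    exogenous_freqs: np.ndarray
    native_allele_index: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("native_freqs", "exogenous_freqs"):
            f = getattr(self, name)
            if f.shape != (self.M, self.alleles_per_marker):
                raise ValueError(f"{name} must have shape (M, A)")
            if not np.allclose(f.sum(axis=1), 1.0):
                raise ValueError(f"{name} rows must sum to 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "M": self.M,
                "alleles_per_marker": self.alleles_per_marker,
                "native_freqs": self.native_freqs.tolist(),
                "exogenous_freqs": self.exogenous_freqs.tolist(),
                "native_allele_index": self.native_allele_index.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "MarkerPanel":
        d = json.loads(s)
        return cls(
            scheme=d["scheme"],
            M=d["M"],
            alleles_per_marker=d["alleles_per_marker"],
            native_freqs=np.asarray(d["native_freqs"], dtype=float),
            exogenous_freqs=np.asarray(d["exogenous_freqs"], dtype=float),
            native_allele_index=np.asarray(d["native_allele_index"], dtype=np.int64),
        )


def make_panel(scheme: str, M: int, native_allele_freq: float | None = None) -> MarkerPanel:
    """Build a marker panel for one of the named frequency schemes.

    ``native_allele_freq`` is required (and only meaningful) for the
    ``extra_diagnostic_like`` scheme, where the native population carries
    allele 1 at frequency ``f`` while the exogenous population is fixed at
    0.5/0.5.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if scheme == "diagnostic":
        nat, exo = [1.0, 0.0], [0.0, 1.0]
    elif scheme == "diagnostic_like":
        nat, exo = [0.8, 0.2], [0.2, 0.8]
    elif scheme == "extra_diagnostic_like":
        if native_allele_freq is None:
            raise ValueError("extra_diagnostic_like requires native_allele_freq")
        f = float(native_allele_freq)
        if not any(np.isclose(f, v) for v in _EXTRA_ALLOWED_F):
            raise ValueError(f"native_allele_freq must be one of {_EXTRA_ALLOWED_F}")
        nat, exo = [f, 1.0 - f], [0.5, 0.5]
    elif scheme == "non_diagnostic":
        nat, exo = [0.80, 0.07, 0.06, 0.07], [0.07, 0.80, 0.06, 0.07]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    nat_a = np.tile(np.asarray(nat, dtype=float), (M, 1))
    exo_a = np.tile(np.asarray(exo, dtype=float), (M, 1))
    return MarkerPanel(
        scheme=scheme,
        M=M,
        alleles_per_marker=len(nat),
        native_freqs=nat_a,
        exogenous_freqs=exo_a,
        native_allele_index=np.zeros(M, dtype=np.int64),
    )


def custom_panel(native_freqs: np.ndarray, exogenous_freqs: np.ndarray) -> MarkerPanel:
    """Panel with arbitrary frequency vectors (no named scheme).

    The native allele per marker is the most frequent allele in the native
    population.
    """
    nat = np.asarray(native_freqs, dtype=float)
    exo = np.asarray(exogenous_freqs, dtype=float)
    return MarkerPanel(
        scheme="custom",
        M=nat.shape[0],
        alleles_per_marker=nat.shape[1],
        native_freqs=nat,
        exogenous_freqs=exo,
        native_allele_index=nat.argmax(axis=1),
    )


def draw_founder_marker_genotype(
    panel: MarkerPanel, origin: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two marker haplotypes of one founder.

    Diagnostic founders are deterministically homozygous for their
    population's private allele; under all other schemes the two allele
    copies are drawn independently from the origin population's
    frequencies (Hardy-Weinberg in the base generation, no linkage
    disequilibrium among markers within an origin group).
    """
    if origin not in ("native", "exogenous"):
        raise ValueError(f"origin must be 'native' or 'exogenous', got {origin!r}")
    if panel.scheme == "diagnostic":
        allele = 0 if origin == "native" else 1
        hap = np.full(panel.M, allele, dtype=np.int8)
        return hap, hap.copy()
    freqs = panel.native_freqs if origin == "native" else panel.exogenous_freqs
    u = rng.random((2, panel.M))
    cum = np.cumsum(freqs, axis=1)
    haps = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
    return haps[0], haps[1]
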