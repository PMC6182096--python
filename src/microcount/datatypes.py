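"""Domain records for microbial enumeration data.

The fundamental datum in enumeration-based microbiology is a raw count of
organisms in a known analytical sample size (a volume, in liters).  A
non-detect is simply an observed count of zero; a TNTC ("too numerous to
count") result is a right-censored count known only to be at least some
threshold.  Legacy reporting collapses the count/volume pair into a single
concentration number, turning zeros into "<1 per volume" strings — the
:class:`ReportedConcentration` record captures that convention so the
legacy estimators can be exercised and compared.

All concentrations are organisms per liter and all volumes are liters;
"per 100 L" figures are display conversions only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

__all__ = [
    "RecoveryModel",
    "PresenceAbsenceTest",
    "CountObservation",
    "ReportedConcentration",
    "Dataset",
    "ValidationError",
    "NonIdentifiableError",
]


class ValidationError(ValueError):
    """Raised when input records violate their domain constraints."""


class NonIdentifiableError(ValueError):
    """Raised when a maximum-likelihood estimate does not exist (e.g. the
    likelihood increases without bound, or all observations are zero)."""


def _check_finite_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class RecoveryModel:
    """Analytical-recovery profile of an enumeration method.

    Recovery is the fraction of organisms in the processed sample that the
    method actually observes.  Three profiles are supported:

    ``perfect``
        every organism in the sample is observed (recovery 1);
    ``constant``
        each organism is independently observed with fixed probability
        ``p`` (Poisson thinning);
    ``beta``
        recovery varies between samples following a Beta(a, b)
        distribution, capturing matrix-to-matrix variability.

    Use the class methods :meth:`perfect`, :meth:`constant` and
    :meth:`beta` rather than the constructor.
    """

    variant: Literal["perfect", "constant", "beta"]
    p: float | None = None
    a: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.variant == "perfect":
            if self.p is not None or self.a is not None or self.b is not None:
                raise ValidationError("perfect recovery takes no parameters")
        elif self.variant == "constant":
            if self.p is None or not math.isfinite(self.p) or not 0 < self.p <= 1:
                raise ValidationError(
                    f"constant recovery requires p in (0, 1], got {self.p!r}"
                )
        elif self.variant == "beta":
            for name in ("a", "b"):
                v = getattr(self, name)
                if v is None or not math.isfinite(v) or v <= 0:
                    raise ValidationError(
                        f"beta recovery requires {name} > 0, got {v!r}"
                    )
        else:  # pragma: no cover - guarded by Literal type
            raise ValidationError(f"unknown recovery variant {self.variant!r}")

    @classmethod
    def perfect(cls) -> "RecoveryModel":
        return cls("perfect")

    @classmethod
    def constant(cls, p: float) -> "RecoveryModel":
        return cls("constant", p=p)

    @classmethod
    def beta(cls, a: float, b: float) -> "RecoveryModel":
        return cls("beta", a=a, b=b)

    @property
    def mean(self) -> float:
        """Mean recovery fraction of the profile."""
        if self.variant == "perfect":
            return 1.0
        if self.variant == "constant":
            return self.p  # type: ignore[return-value]
        return self.a / (self.a + self.b)  # type: ignore[operator]

    def sample(self, rng, size: int):
        """Draw per-sample recovery fractions with numpy Generator *rng*."""
        import numpy as np

        if self.variant == "perfect":
            return np.ones(size)
        if self.variant == "constant":
            return np.full(size, self.p)
        return rng.beta(self.a, self.b, size=size)

    @classmethod
    def parse(cls, text: str) -> "RecoveryModel":
        """Parse ``perfect``, ``constant:<p>`` or ``beta:<a>,<b>``."""
        text = text.strip().lower()
        if text == "perfect":
            return cls.perfect()
        if text.startswith("constant:"):
            return cls.constant(float(text.split(":", 1)[1]))
        if text.startswith("beta:"):
            a, b = text.split(":", 1)[1].split(",")
            return cls.beta(float(a), float(b))
        raise ValidationError(
            f"cannot parse recovery spec {text!r}; expected 'perfect', "
            "'constant:<p>' or 'beta:<a>,<b>'"
        )

    def __str__(self) -> str:
        if self.variant == "perfect":
            return "perfect"
        if self.variant == "constant":
            return f"constant({self.p:g})"
        return f"beta({self.a:g},{self.b:g})"


@dataclass(frozen=True)
class PresenceAbsenceTest:
    """A single presence/absence test: an aliquot volume and its outcome."""

    volume: float
    positive: bool

    def __post_init__(self) -> None:
        _check_finite_positive("volume", self.volume)


@dataclass(frozen=True)
class CountObservation:
    """A raw enumeration result: organisms counted in a known volume.

    Either ``count`` (an exact non-negative integer) or ``tntc_threshold``
    (the count is only known to be >= threshold) is set, never both.
    """

    sample_id: str
    count: int | None
    volume: float
    tntc_threshold: int | None = None

    def __post_init__(self) -> None:
        _check_finite_positive("volume", self.volume)
        if (self.count is None) == (self.tntc_threshold is None):
            raise ValidationError(
                "exactly one of count / tntc_threshold must be given"
            )
        if self.count is not None:
            if self.count != int(self.count) or self.count < 0:
                raise ValidationError(
                    f"count must be a non-negative integer, got {self.count!r}"
                )
        if self.tntc_threshold is not None:
            if self.tntc_threshold != int(self.tntc_threshold) or self.tntc_threshold < 1:
                raise ValidationError(
                    f"TNTC threshold must be an integer >= 1, got {self.tntc_threshold!r}"
                )

    @property
    def is_tntc(self) -> bool:
        return self.tntc_threshold is not None

    @property
    def is_nondetect(self) -> bool:
        return self.count == 0


@dataclass(frozen=True)
class ReportedConcentration:
    """A legacy per-sample report: a concentration, or an ND with a limit.

    Detects carry ``value`` (organisms/L); non-detects carry
    ``nondetect=True`` and ``limit``, the per-sample purported detection
    limit 1/volume (organisms/L).
    """

    sample_id: str
    value: float | None = None
    nondetect: bool = False
    limit: float | None = None

    def __post_init__(self) -> None:
        if self.nondetect:
            if self.value is not None or self.limit is None:
                raise ValidationError(
                    "a non-detect record needs limit and no value"
                )
            _check_finite_positive("limit", self.limit)
        else:
            if self.value is None or self.limit is not None:
                raise ValidationError("a detect record needs value and no limit")
            _check_finite_positive("value", self.value)


@dataclass
class Dataset:
    """A homogeneous collection of count or reported-concentration records."""

    records: list
    kind: Literal["counts", "reported"]
    units: Literal["per-L", "per-100L"] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        expected = CountObservation if self.kind == "counts" else ReportedConcentration
        for r in self.records:
            if not isinstance(r, expected):
                raise ValidationError(
                    f"dataset of kind {self.kind!r} cannot hold {type(r).__name__}"
                )
        if self.kind == "reported" and self.units is None:
            raise ValidationError("reported datasets require a units tag")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)
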