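"""The basic data record: one pool sequence with its affinity and profile."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .structure import AnnotationProfile

GROUP_STEMLOOP = "stem-loop"
GROUP_WEAK = "weakly-structured"


@dataclass
class RnaRecord:
    """One RNA with an optional measured affinity and annotation profile."""

    id: str
    seq: str
    affinity: Optional[float] = None
    group: Optional[str] = None
    profile: Optional[AnnotationProfile] = field(default=None, repr=False)

    def with_profile(self, profile: AnnotationProfile) -> "RnaRecord":
        return replace(self, profile=profile)

    def with_affinity(self, affinity: float) -> "RnaRecord":
        return replace(self, affinity=affinity)
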