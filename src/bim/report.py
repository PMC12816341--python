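"""Aggregated measure report: the JSON-facing summary of one analysis."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .measures import TimeDomainMeasures
from .spectral import BandIntegral

__all__ = ["MeasureReport"]


@dataclass
class MeasureReport:
    """Time-domain measures, band-integrated measures and significance flags.

    ``domain`` records how the numbers were obtained ("time", "population",
    "knn", ...); units are nats for all information measures.
    """

    domain: str
    measures: TimeDomainMeasures | None = None
    bands: list[BandIntegral] = field(default_factory=list)
    significance: dict = field(default_factory=dict)
    model_meta: dict = field(default_factory=dict)

    def as_dict(self, bits: bool = False) -> dict:
        d = {"domain": self.domain, "units": "bits" if bits else "nats",
             "model_meta": self.model_meta}
        if self.measures is not None:
            d["measures"] = self.measures.as_dict(bits=bits)
            d["measures_raw"] = self.measures.raw
        if self.bands:
            d["bands"] = [b.as_dict() for b in self.bands]
        if self.significance:
            d["significance"] = self.significance
        return d

    def to_json(self, path: str | Path | None = None, **kw) -> str:
        text = json.dumps(self.as_dict(**kw), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text
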