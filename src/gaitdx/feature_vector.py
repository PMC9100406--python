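"""Named feature vector container shared by the EMG and GRF feature banks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedFeatureError


@dataclass
class FeatureVector:
    """Ordered, uniquely named, finite feature values.

    Names are channel-qualified, e.g. ``GL__LMAV``.
    """

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise UndefinedFeatureError(
                f"{len(self.names)} names vs {len(self.values)} values"
            )
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise UndefinedFeatureError(f"duplicate feature names: {dupes}")
        bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
        if bad:
            raise UndefinedFeatureError(f"non-finite feature values: {bad}")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    @staticmethod
    def concat(vectors: list["FeatureVector"]) -> "FeatureVector":
        names: list[str] = []
        values: list[np.ndarray] = []
        for v in vectors:
            names.extend(v.names)
            values.append(v.values)
        return FeatureVector(names, np.concatenate(values))
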