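"""Pedigree records: (id, sire, dam, sex, generation) with 0 = unknown parent.

Ids are positive integers; records must be ordered parents-before-offspring
and founders (generation 0) have both parents unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PedigreeError


@dataclass
class Pedigree:
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    sire: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    dam: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    sex: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    generation: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        for name in ("ids", "sire", "dam", "sex", "generation"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def max_id(self) -> int:
        return int(self.ids.max()) if self.n else 0

    def append_cohort(
        self,
        ids: np.ndarray,
        sire: np.ndarray,
        dam: np.ndarray,
        sex: np.ndarray,
        generation: np.ndarray | int,
    ) -> None:
        ids = np.asarray(ids, dtype=np.int64)
        if np.isscalar(generation) or np.ndim(generation) == 0:
            generation = np.full(ids.size, int(generation), dtype=np.int64)
        self.ids = np.concatenate([self.ids, ids])
        self.sire = np.concatenate([self.sire, np.asarray(sire, dtype=np.int64)])
        self.dam = np.concatenate([self.dam, np.asarray(dam, dtype=np.int64)])
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.int64)])
        self.generation = np.concatenate(
            [self.generation, np.asarray(generation, dtype=np.int64)]
        )

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of each individual's parents (-1 for unknown).

        Validates that ids are unique and that every known parent appears in
        an earlier row (which also rules out cycles).
        """
        pos: dict[int, int] = {}
        for i, ident in enumerate(self.ids):
            if ident in pos:
                raise PedigreeError(f"duplicate id {ident}")
            if ident <= 0:
                raise PedigreeError("ids must be positive")
            pos[int(ident)] = i
        sire_idx = np.empty(self.n, dtype=np.int64)
        dam_idx = np.empty(self.n, dtype=np.int64)
        for i in range(self.n):
            for arr, out in ((self.sire, sire_idx), (self.dam, dam_idx)):
                p = int(arr[i])
                if p == 0:
                    out[i] = -1
                    continue
                j = pos.get(p)
                if j is None:
                    raise PedigreeError(f"parent {p} of {self.ids[i]} not in pedigree")
                if j >= i:
                    raise PedigreeError(
                        f"parent {p} does not precede offspring {self.ids[i]}"
                    )
                out[i] = j
        return sire_idx, dam_idx

    def validate(self) -> None:
        self.parent_indices()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": self.sire,
                "dam": self.dam,
                "sex": self.sex,
                "generation": self.generation,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(
            df["id"].to_numpy(),
            df["sire"].to_numpy(),
            df["dam"].to_numpy(),
            df["sex"].to_numpy() if "sex" in df else np.zeros(len(df)),
            df["generation"].to_numpy() if "generation" in df else np.zeros(len(df)),
        )

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
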