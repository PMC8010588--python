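"""Weinberg differential method for twin zygosity composition.

Dizygotic co-twins have independent sexes, so among DZ pairs same-sex and
opposite-sex are equally likely; monozygotic pairs are always same-sex.  The
Weinberg rule therefore estimates the DZ pair count as twice the
opposite-sex pair count, with MZ as the remainder, and the mean genetic
resemblance of the twin set as the MZ/DZ-weighted mean of 1.0 and 0.5.

Counts are of pairs (one row per pair, not double-entered).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


class ZygosityError(ValueError):
    """The Weinberg assumption is violated (more opposite- than same-sex
    pairs would imply a negative MZ count)."""


@dataclass(frozen=True)
class ZygosityEstimate:
    n_opposite_sex: int
    n_same_sex: int

    @property
    def n_dz(self) -> int:
        return 2 * self.n_opposite_sex

    @property
    def n_mz(self) -> int:
        return (self.n_same_sex + self.n_opposite_sex) - self.n_dz

    @property
    def mean_resemblance(self) -> float:
        total = self.n_mz + self.n_dz
        if total == 0:
            raise ZygosityError("no twin pairs")
        return (self.n_mz * 1.0 + self.n_dz * 0.5) / total

    def display(self) -> str:
        return (f"opposite-sex pairs: {self.n_opposite_sex}\n"
                f"same-sex pairs:     {self.n_same_sex}\n"
                f"DZ pairs (Weinberg): {self.n_dz}\n"
                f"MZ pairs (Weinberg): {self.n_mz}\n"
                f"mean genetic resemblance: {self.mean_resemblance:.2f}")


def weinberg(n_opposite_sex: int, n_same_sex: int) -> ZygosityEstimate:
    """Estimate MZ/DZ composition from de-duplicated twin-pair sex counts."""
    if n_opposite_sex < 0 or n_same_sex < 0:
        raise ZygosityError("pair counts must be nonnegative")
    est = ZygosityEstimate(n_opposite_sex, n_same_sex)
    if est.n_mz < 0:
        raise ZygosityError(
            f"negative MZ estimate ({est.n_mz}): more opposite-sex than "
            "same-sex pairs violates the Weinberg assumption")
    return est


def weinberg_from_pairs(twin_pairs: pd.DataFrame, persons: pd.DataFrame
                        ) -> ZygosityEstimate:
    """Apply the Weinberg method to a (possibly double-entered) twin pair
    table using the person table's sexes."""
    dedup = twin_pairs.copy()
    a = dedup[["index_id", "relative_id"]].min(axis=1)
    b = dedup[["index_id", "relative_id"]].max(axis=1)
    dedup = pd.DataFrame({"a": a, "b": b}).drop_duplicates()
    sex = persons.set_index("person_id")["sex"]
    opp = (sex.reindex(dedup["a"]).to_numpy()
           != sex.reindex(dedup["b"]).to_numpy())
    return weinberg(int(opp.sum()), int((~opp).sum()))
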