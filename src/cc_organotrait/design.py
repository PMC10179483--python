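"""Study design: which lines, how many animals per (line, sex, diet) cell,
and the measurement schedule."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["StudyDesign", "default_design", "DesignError", "SEXES", "DIETS"]

SEXES = ("F", "M")
DIETS = ("CHD", "HFD")

# Per-cell animal counts of the default 8-line cohort, keyed
# (line, sex, diet).  Column order below: F-CHD, M-CHD, F-HFD, M-HFD.
_DEFAULT_COUNTS = {
    "IL72": (4, 4, 4, 6),
    "IL557": (6, 3, 8, 5),
    "IL711": (7, 4, 7, 5),
    "IL1912": (10, 9, 7, 8),
    "IL2513": (4, 5, 3, 7),
    "IL3912": (4, 10, 10, 7),
    "IL4141": (4, 8, 7, 6),
    "IL5000": (7, 5, 14, 9),
}

DEFAULT_WEEKS = (0, 2, 4, 6, 8, 10, 12)
DEFAULT_IPGTT_WEEKS = (6, 12)
DEFAULT_IPGTT_TIMEPOINTS_MIN = (0, 15, 30, 60, 120, 180)


class DesignError(ValueError):
    """Raised when a StudyDesign violates its invariants."""


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: lines, per-cell group sizes and measurement schedule.

    Parameters
    ----------
    lines:
        Ordered line identifiers.
    group_sizes:
        Mapping ``(line, sex, diet) -> animal count``. Sex in {"F", "M"},
        diet in {"CHD", "HFD"}. Missing cells count as zero.
    weeks:
        Body-weight measurement weeks, ascending, starting at the
        challenge start (week 0).
    ipgtt_weeks:
        Weeks at which a glucose tolerance test is run; subset of *weeks*.
    ipgtt_timepoints_min:
        Minutes after glucose injection at which blood glucose is read;
        strictly increasing, first must be 0.
    """

    lines: tuple[str, ...]
    group_sizes: dict[tuple[str, str, str], int]
    weeks: tuple[int, ...] = DEFAULT_WEEKS
    ipgtt_weeks: tuple[int, ...] = DEFAULT_IPGTT_WEEKS
    ipgtt_timepoints_min: tuple[int, ...] = DEFAULT_IPGTT_TIMEPOINTS_MIN

    def __post_init__(self) -> None:
        if not self.lines:
            raise DesignError("design needs at least one line")
        for key, n in self.group_sizes.items():
            if len(key) != 3 or key[1] not in SEXES or key[2] not in DIETS:
                raise DesignError(f"malformed group-size key {key!r}")
            if key[0] not in self.lines:
                raise DesignError(f"group size for unknown line {key[0]!r}")
            if n < 0:
                raise DesignError(f"negative count {n} for cell {key!r}")
        if list(self.weeks) != sorted(set(self.weeks)):
            raise DesignError("weeks must be strictly increasing")
        if not set(self.ipgtt_weeks) <= set(self.weeks):
            raise DesignError("ipgtt_weeks must be a subset of weeks")
        t = self.ipgtt_timepoints_min
        if len(t) < 2 or list(t) != sorted(set(t)) or t[0] != 0:
            raise DesignError(
                "ipgtt timepoints must be strictly increasing and start at 0"
            )

    def count(self, line: str, sex: str, diet: str) -> int:
        return self.group_sizes.get((line, sex, diet), 0)

    @property
    def n_total(self) -> int:
        return sum(self.group_sizes.values())

    def cells(self):
        """Yield (line, sex, diet, count) for every non-empty cell in a
        stable order (line, then F/M, then CHD/HFD)."""
        for line in self.lines:
            for sex in SEXES:
                for diet in DIETS:
                    n = self.count(line, sex, diet)
                    if n:
                        yield line, sex, diet, n


def default_design() -> StudyDesign:
    """The default 8-line, 207-animal design with its printed per-cell counts."""
    sizes: dict[tuple[str, str, str], int] = {}
    for line, (f_chd, m_chd, f_hfd, m_hfd) in _DEFAULT_COUNTS.items():
        sizes[(line, "F", "CHD")] = f_chd
        sizes[(line, "M", "CHD")] = m_chd
        sizes[(line, "F", "HFD")] = f_hfd
        sizes[(line, "M", "HFD")] = m_hfd
    return StudyDesign(lines=tuple(_DEFAULT_COUNTS), group_sizes=sizes)
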