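"""Study design: breeding lines, their roles, and the replicate structure.

The comparative design used throughout the package contrasts genetically
engineered (GE) lines against their shared parental line and against
conventionally bred lines of a different genetic background.  Every omics
matrix, differential comparison, and enrichment run resolves its samples
against a :class:`StudyDesign`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

GE = "ge"
PARENT = "parent"
CONVENTIONAL = "conventional"
ROLES = frozenset({GE, PARENT, CONVENTIONAL})

#: The six maize lines of the reference design: three RNAi-based GE
#: transformants of the same parent, the parent, and two related
#: conventionally bred lines.
DEFAULT_LINES = ("DTS_108", "DTS_123", "DTS_127", "TJ806", "AR02", "AR03")
DEFAULT_ROLES: Mapping[str, str] = {
    "DTS_108": GE,
    "DTS_123": GE,
    "DTS_127": GE,
    "TJ806": PARENT,
    "AR02": CONVENTIONAL,
    "AR03": CONVENTIONAL,
}


@dataclass(frozen=True, eq=True)
class StudyDesign:
    """Lines, breeding roles, and replicate count for one experiment.

    Parameters
    ----------
    lines
        Unique line identifiers.  Sample names are formed as
        ``"{line}_{replicate}"`` with 1-based replicate numbers.
    roles
        Mapping line -> role, each role one of ``"ge"``, ``"parent"``,
        ``"conventional"``.  When any GE line is present exactly one
        parent is required.
    replicates_per_line
        Biological replicates per line; at least 2 so group tests have
        degrees of freedom.
    seed
        Base seed recorded with the design; generators derive their own
        streams from it.
    """

    lines: tuple[str, ...] = DEFAULT_LINES
    roles: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))
    replicates_per_line: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("line identifiers must be unique")
        if not self.lines:
            raise ValueError("at least one line is required")
        if self.replicates_per_line < 2:
            raise ValueError("replicates_per_line must be >= 2")
        missing = [ln for ln in self.lines if ln not in self.roles]
        if missing:
            raise ValueError(f"lines without a role: {missing}")
        bad = {ln: r for ln, r in self.roles.items() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown roles: {bad}")
        n_parent = sum(1 for ln in self.lines if self.roles[ln] == PARENT)
        n_ge = sum(1 for ln in self.lines if self.roles[ln] == GE)
        if n_ge > 0 and n_parent != 1:
            raise ValueError("exactly one parent line is required when GE lines exist")

    # -- sample bookkeeping -------------------------------------------------

    def role(self, line: str) -> str:
        if line not in self.roles:
            raise ValueError(f"unknown line: {line!r}")
        return self.roles[line]

    @property
    def samples(self) -> list[str]:
        """All sample names, line-major, replicates 1..r."""
        return [
            f"{line}_{rep}"
            for line in self.lines
            for rep in range(1, self.replicates_per_line + 1)
        ]

    def samples_for(self, line: str) -> list[str]:
        if line not in self.roles:
            raise ValueError(f"unknown line: {line!r}")
        return [f"{line}_{rep}" for rep in range(1, self.replicates_per_line + 1)]

    def line_of(self, sample: str) -> str:
        """Resolve a ``line_rep`` sample name back to its line."""
        line, _, rep = sample.rpartition("_")
        if line in self.roles and rep.isdigit():
            return line
        raise ValueError(f"sample name {sample!r} does not resolve to a design line")

    def lines_with_role(self, role: str) -> list[str]:
        return [ln for ln in self.lines if self.roles[ln] == role]
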