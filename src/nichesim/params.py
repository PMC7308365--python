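"""Model parameters for the niche-construction interacting particle system."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class ModelParams:
    """Reaction rates and neighborhood ranges.

    The model is a contact process on an ephemeral landscape.  Occupied
    sites go extinct at rate ``delta`` and every non-destroyed site is
    destroyed at rate ``e``.  A niche constructor (NC) colonizes vacant
    neighbors within range ``r_col`` at rate ``(1 - c)**alpha`` and renews
    destroyed sites within range ``r_con`` back to vacant at rate ``c`` --
    construction allocation ``c`` is paid for by the colonization discount
    ``(1 - c)**alpha``.  With ``competition`` enabled a second occupied
    strategy (the exploiter, a plain contact process with ``c = 0`` and
    colonization rate 1) shares the lattice and competes for vacant sites.

    Parameters
    ----------
    delta : float
        Extinction rate per occupied site (>= 0).
    e : float
        Destruction rate per non-destroyed site (>= 0); patch lifetime is
        ``1 / e``.
    c : float
        Construction allocation in [0, 1].
    alpha : float
        Trade-off exponent (>= 0); ``alpha = 0`` makes construction free.
    r_col : int
        Colonization range r* (von Neumann ball); default 1, i.e. the four
        nearest neighbors.
    r_con : int or None
        Construction range r; ``None`` means equal to ``r_col``.  Ignored
        when ``global_construction`` is set.
    global_construction : bool
        If True the construction neighborhood is the whole lattice
        (construction targets are drawn uniformly over all sites).
    competition : bool
        Enable the exploiter strategy.
    """

    delta: float
    e: float = 0.0
    c: float = 0.0
    alpha: float = 1.0
    r_col: int = 1
    r_con: int | None = None
    global_construction: bool = False
    competition: bool = False

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.e < 0:
            raise ValueError(f"e must be >= 0, got {self.e}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must lie in [0, 1], got {self.c}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.r_col < 1:
            raise ValueError(f"r_col must be >= 1, got {self.r_col}")
        if self.r_con is not None and self.r_con < 1:
            raise ValueError(f"r_con must be >= 1 or None, got {self.r_con}")

    @property
    def beta(self) -> float:
        """Effective NC colonization rate ``(1 - c)**alpha``.

        ``0**0`` is taken as 1 (``alpha = 0`` means no colonization cost even
        at full allocation).
        """
        return (1.0 - self.c) ** self.alpha

    @property
    def construction_range(self) -> int:
        """Resolved construction range (``r_con`` defaulting to ``r_col``)."""
        return self.r_col if self.r_con is None else self.r_con

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)
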