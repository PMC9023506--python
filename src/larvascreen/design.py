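"""Cohort bookkeeping for the primary screen and follow-up experiments.

These constants describe the published screen design (library sizes, session
structure, control group sizes and the reported hit count) so that cohort
arithmetic — larvae per drug, total larvae, hit rate, results-file row counts
— is computed rather than quoted.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import plates


@dataclass(frozen=True)
class ScreenDesign:
    """Design of a multi-session small-molecule behavioral screen."""

    #: drugs per library plate (the screened library ships as three plates)
    library_plates: tuple[int, ...] = (80, 80, 30)
    #: imaging sessions run for each library plate
    sessions_per_library_plate: int = 12
    #: wells per drug per session (one well on each of the four 96-well plates)
    duplicate_wells_per_session: int = 4
    #: control larvae across all sessions
    untreated_larvae: int = 960
    dmso_larvae: int = 864
    #: control larvae left after the 1% immobility exclusion
    untreated_included: int = 952
    dmso_included: int = 844
    #: drugs with at least one behavior significant at the 0.05/m tier
    significant_drugs: int = 51
    #: frames per well in one 3-h recording
    frames_per_well: int = 1800
    wells_per_session: int = 4 * plates.WELLS_PER_PLATE

    @property
    def n_drugs(self) -> int:
        return sum(self.library_plates)

    @property
    def larvae_per_drug(self) -> int:
        return self.sessions_per_library_plate * self.duplicate_wells_per_session

    @property
    def treated_larvae(self) -> int:
        return self.n_drugs * self.larvae_per_drug

    @property
    def total_larvae(self) -> int:
        return self.untreated_larvae + self.dmso_larvae + self.treated_larvae

    @property
    def hit_rate_pct(self) -> float:
        return 100.0 * self.significant_drugs / self.n_drugs

    @property
    def results_rows_per_session(self) -> int:
        """Rows in one session's image-analysis results file (wells x images)."""
        return self.wells_per_session * self.frames_per_well


#: the FDA-approved-drug screen analysed by this package
TOCRIS_SCREEN = ScreenDesign()
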