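"""Brute-force per-vial, per-dose replay of the multi-dose vial policy.

Independent oracle for clinic sessions: every vial is its own object,
every arriving child is processed one dose at a time.  Used only to
cross-check the engine's aggregated session accounting.
"""

from dataclasses import dataclass, field

from vaxchain.catalog import VaccinePresentation


@dataclass
class _OracleVial:
    doses_left: int
    opened_at: float | None = None


@dataclass
class OracleClinic:
    """Single-antigen clinic state for the replay."""

    presentation: VaccinePresentation
    sealed: list[_OracleVial] = field(default_factory=list)  # FIFO order
    open_vials: list[_OracleVial] = field(default_factory=list)

    def stock_sealed(self, n: int) -> None:
        self.sealed.extend(
            _OracleVial(self.presentation.doses_per_vial) for _ in range(n)
        )

    def run_session(self, n_arrivals: int, now: float) -> dict:
        p = self.presentation
        waste = 0
        # discard open vials past their opened-vial lifetime
        still_open = []
        for v in self.open_vials:
            lifetime = p.open_vial_lifetime_days or 0.0
            if v.opened_at is not None and now >= v.opened_at + lifetime:
                waste += v.doses_left
            else:
                still_open.append(v)
        self.open_vials = still_open

        administered = missed = opened = 0
        for _child in range(n_arrivals):
            vial = None
            for v in self.open_vials:
                if v.doses_left > 0:
                    vial = v
                    break
            if vial is None and self.sealed:
                vial = self.sealed.pop(0)
                vial.opened_at = now
                self.open_vials.append(vial)
                opened += 1
            if vial is None:
                missed += 1
                continue
            vial.doses_left -= 1
            administered += 1

        if p.formulation == "lyophilized":
            for v in self.open_vials:
                waste += v.doses_left
            self.open_vials = []
        else:
            self.open_vials = [v for v in self.open_vials if v.doses_left > 0]
        return {
            "arrivals": n_arrivals,
            "administered": administered,
            "missed": missed,
            "vials_opened": opened,
            "open_vial_waste": waste,
        }
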