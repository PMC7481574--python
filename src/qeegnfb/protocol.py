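"""Rule-based QEEG-informed neurofeedback protocol assignment.

Maps a subject's resting-state QEEG feature set (plus a sleep-problem
flag) to one of five protocol families and a concrete session
configuration, recording every fired rule in a rationale trace. Rule
precedence (fixed, logged):

1. excess fronto-central slowing → theta/beta (TBR) training at the
   midline site of maximal theta, inhibiting the individualized theta
   sub-band; beta reward only when beta is not elevated and no spindles;
2. excess frontal alpha → frontal-alpha down-training at midline;
3. spindling or excess beta → beta down-training at the fronto-central
   site of maximal spindle power, inhibiting centre ± 2 Hz;
4. low-voltage EEG → SMR/SCP with eyes-closed alpha up-training at Pz;
5. otherwise SMR (the default family), replaced by SCP when excess mu
   rhythm overlaps the SMR band.

Spindles or frontal alpha can additionally fire as an adjunct protocol
when another rule wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import BANDS, THETA_SUBBANDS, Band, QEEGFeatures

MIDLINE_SITES = ("Fz", "FCz", "Cz")
SMR_SITES = ("C3", "Cz", "C4")

#: Beta reward band for TBR / frontal-alpha protocols.
BETA_REWARD = Band("beta_reward", 20.0, 25.0)
SMR_REWARD = BANDS["smr"]
#: Half-width of the inhibit band around a detected spindle centre (Hz).
SPINDLE_INHIBIT_HALFWIDTH = 2.0

EMG_INHIBIT = BANDS["emg"]


@dataclass
class ProtocolDecision:
    primary_protocol: str  # TBR | SMR | SCP | FrontalAlpha | BetaDown
    sites: list[str]
    reward_band: Band | None
    inhibit_bands: list[Band]
    adjunct: list[str] = field(default_factory=list)
    rationale: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.reward_band is not None:
            for b in self.inhibit_bands:
                if b.lo < self.reward_band.hi and self.reward_band.lo < b.hi:
                    raise ValueError(
                        f"reward {self.reward_band.name} overlaps inhibit {b.name}"
                    )


@dataclass
class SessionConfig:
    duration_min: float = 25.0
    block_min: float = 5.0
    inter_block_break_min: float = 1.0
    reinforcement_target: float = 0.30  # fraction of time rewarded
    smr_time_above_threshold_s: float | None = None  # SMR only, 0.2–0.5 s
    emg_inhibit_band: Band = EMG_INHIBIT
    emg_threshold_uv: float = 7.5

    def __post_init__(self) -> None:
        if not (20 <= self.duration_min <= 30):
            raise ValueError("session duration must be 20–30 min")
        if not (0.25 <= self.reinforcement_target <= 0.40):
            raise ValueError("reinforcement target must be 25–40%")
        if self.smr_time_above_threshold_s is not None and not (
            0.2 <= self.smr_time_above_threshold_s <= 0.5
        ):
            raise ValueError("SMR time-above-threshold must be 0.2–0.5 s")
        if not (5.0 <= self.emg_threshold_uv <= 10.0):
            raise ValueError("EMG threshold must be 5–10 μV")


def _beta_elevated(features: QEEGFeatures) -> bool:
    # beta is "elevated" when spindling beta was detected; a coarser
    # z-based beta excess could be added to the feature set later
    return features.beta_spindles


def assign_protocol(features: QEEGFeatures, sleep_problems: bool = False) -> ProtocolDecision:
    """Deterministic protocol assignment with a rationale trace."""
    trace: list[str] = []
    adjunct: list[str] = []

    theta_site = max(
        MIDLINE_SITES, key=lambda s: features.band_power.get((s, "theta"), 0.0)
    )
    spindle_site = features.beta_spindle_site or "FCz"

    if features.excess_slowing:
        trace.append(
            "rule 1: excess fronto-central slowing -> theta/beta protocol "
            f"at midline site of maximal theta ({theta_site})"
        )
        sub = features.theta_subband
        inhibit = [THETA_SUBBANDS[sub if sub in THETA_SUBBANDS else "default"]]
        trace.append(f"theta inhibit individualized to {inhibit[0].lo:g}-{inhibit[0].hi:g} Hz")
        if _beta_elevated(features):
            reward = None
            trace.append("beta elevated or spindling: beta reward withheld")
        else:
            reward = BETA_REWARD
            trace.append("beta not elevated: reward 20-25 Hz")
        decision = ProtocolDecision(
            "TBR", [theta_site], reward, inhibit, adjunct, trace
        )
    elif features.frontal_alpha_excess:
        trace.append("rule 2: excess frontal alpha (EO) -> frontal alpha protocol at midline")
        reward = None if _beta_elevated(features) else BETA_REWARD
        if reward is None:
            trace.append("beta elevated or spindling: beta reward withheld")
        decision = ProtocolDecision(
            "FrontalAlpha", list(MIDLINE_SITES), reward, [BANDS["alpha"]], adjunct, trace
        )
    elif features.beta_spindles:
        c = features.beta_spindle_center_hz
        lo = max(0.5, c - SPINDLE_INHIBIT_HALFWIDTH)
        trace.append(
            f"rule 3: beta spindles at {spindle_site} (centre {c:.1f} Hz) -> "
            f"beta down-training, inhibit {lo:g}-{c + SPINDLE_INHIBIT_HALFWIDTH:g} Hz"
        )
        decision = ProtocolDecision(
            "BetaDown",
            [spindle_site],
            None,
            [Band("spindle_inhibit", lo, c + SPINDLE_INHIBIT_HALFWIDTH)],
            adjunct,
            trace,
        )
    elif features.low_voltage:
        trace.append("rule 4: low-voltage EEG -> SMR/SCP with EC alpha up-training at Pz")
        adjunct.append("AlphaUp@Pz")
        decision = ProtocolDecision(
            "SMR", list(SMR_SITES), SMR_REWARD, [BANDS["theta"]], adjunct, trace
        )
    else:
        if features.mu_excess:
            trace.append(
                "rule 5: no band deviation; excess mu overlaps the SMR band -> SCP preferred"
            )
            decision = ProtocolDecision("SCP", ["Cz"], None, [], adjunct, trace)
        else:
            why = "sleep problems" if sleep_problems else "no clear QEEG deviation"
            trace.append(f"rule 5: {why} -> SMR protocol (default family)")
            decision = ProtocolDecision(
                "SMR", list(SMR_SITES), SMR_REWARD, [BANDS["theta"]], adjunct, trace
            )

    # adjunct protocols: deviations that did not decide the primary
    if features.beta_spindles and decision.primary_protocol != "BetaDown":
        adjunct.append("BetaDown")
        trace.append("adjunct: spindling beta down-training added as second protocol")
    if features.frontal_alpha_excess and decision.primary_protocol != "FrontalAlpha":
        adjunct.append("FrontalAlpha")
        trace.append("adjunct: frontal alpha down-training added as second protocol")
    return decision


def build_session_config(decision: ProtocolDecision) -> SessionConfig:
    """Session parameters for a decision, at mid-range defaults.

    25-minute sessions in 5-minute blocks with ≥1 minute breaks, a 30%
    effective-reinforcement target, the 55–100 Hz EMG inhibit at 7.5 μV
    on every protocol, and a 0.35 s time-above-threshold for SMR reward.
    """
    smr_t = 0.35 if decision.primary_protocol == "SMR" else None
    return SessionConfig(smr_time_above_threshold_s=smr_t)
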