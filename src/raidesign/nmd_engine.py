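"""NMD-fate classification of premature termination codons.

Implements the NMDetective-B nested decision rules: a PTC evades NMD
(i) if it lies in the last exon, (ii) in the last 50 nt of the
penultimate exon, or (iii) less than 150 nt from the start codon; a PTC
in a long exon (>407 nt) triggers NMD only inefficiently and is called
``attenuated``; anything else is ``targeted``.  The tests are applied
strictly in order, so a last-exon PTC never reports the long-exon rule.

A per-product composite degradation score aggregates the number of
NMD-targeted PTCs, the long-3'UTR flag (>800 nt) and the number of PTCs
inside the 55-400 nt junction window.  The aggregation weights are an
explicit design choice of this package — they exist only to order
candidates and are surfaced in every report.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RuleConfig
from .splice_outcome_sim import PTC, SpliceProduct, count_ptcs_in_window

NMD_RULES = ("last_exon", "penultimate_tail_50", "start_proximal_150",
             "long_exon_407", "none")


@dataclass(frozen=True)
class NmdVerdict:
    ptc: PTC
    verdict: str  # targeted | evading | attenuated
    triggered_rule: str  # one of NMD_RULES
    notes: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in {"targeted", "evading", "attenuated"}:
            raise ValueError(f"bad verdict {self.verdict!r}")
        if self.triggered_rule not in NMD_RULES:
            raise ValueError(f"bad rule {self.triggered_rule!r}")
        if self.verdict == "targeted" and self.triggered_rule != "none":
            raise ValueError("targeted PTCs must not trigger an evasion rule")
        if self.verdict == "evading" and self.triggered_rule in {"none", "long_exon_407"}:
            raise ValueError("evading PTCs must name the evasion rule")


@dataclass(frozen=True)
class DegradationScore:
    scenario: str
    n_ptcs_targeted: int
    n_ptcs_in_55_400_window: int
    long_utr3: bool
    composite: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.composite <= 1.0:
            raise ValueError(f"composite {self.composite} outside [0, 1]")


def _containing_exon_length(ptc: PTC, product: SpliceProduct) -> int:
    """Length of the product 'exon' (inter-junction segment) holding the PTC."""
    bounds = [0, *product.junctions, len(product.mrna)]
    for lo, hi in zip(bounds, bounds[1:]):
        if lo <= ptc.position < hi:
            return hi - lo
    raise ValueError("PTC outside the product")  # pragma: no cover


def classify_nmd(ptc: PTC, product: SpliceProduct,
                 config: RuleConfig | None = None) -> NmdVerdict:
    """NMDetective-B nested tests, applied in order (i) -> (iv)."""
    config = config or RuleConfig()
    if ptc.in_last_exon:
        return NmdVerdict(ptc, "evading", "last_exon",
                          "no downstream junction to mark")
    if ptc.in_penultimate_tail:
        return NmdVerdict(ptc, "evading", "penultimate_tail_50",
                          f"within {config.nmdetective_penultimate_tail} nt of "
                          "the final junction")
    if ptc.distance_from_start_codon < config.nmdetective_start_proximal:
        return NmdVerdict(ptc, "evading", "start_proximal_150",
                          "translation-reinitiation zone")
    if _containing_exon_length(ptc, product) > config.nmdetective_long_exon:
        return NmdVerdict(ptc, "attenuated", "long_exon_407",
                          "NMD becomes less efficient far upstream of the junction")
    return NmdVerdict(ptc, "targeted", "none")


def utr3_flag(product: SpliceProduct, config: RuleConfig | None = None) -> bool:
    """True when the product's 3'UTR (first stop to polyA) exceeds the
    long-3'UTR degradation threshold (strict inequality)."""
    config = config or RuleConfig()
    return product.utr3_len > config.long_utr3_threshold


def degradation_score(product: SpliceProduct, verdicts: list[NmdVerdict],
                      config: RuleConfig | None = None) -> DegradationScore:
    """Composite degradation likelihood in [0, 1], monotone in each input:

    ``w_t * min(1, n_targeted/3) + w_u * long_utr3 + w_w * min(1, n_window/3)``
    with default weights (0.6, 0.25, 0.15).
    """
    config = config or RuleConfig()
    n_targeted = sum(1 for v in verdicts if v.verdict == "targeted")
    n_window = count_ptcs_in_window(product.ptcs, config)
    long_utr = utr3_flag(product, config)
    composite = (
        config.weight_targeted * min(1.0, n_targeted / 3.0)
        + config.weight_long_utr3 * (1.0 if long_utr else 0.0)
        + config.weight_in_window * min(1.0, n_window / 3.0)
    )
    total_weight = (config.weight_targeted + config.weight_long_utr3
                    + config.weight_in_window)
    composite = min(composite, total_weight, 1.0)
    return DegradationScore(
        scenario=product.scenario,
        n_ptcs_targeted=n_targeted,
        n_ptcs_in_55_400_window=n_window,
        long_utr3=long_utr,
        composite=round(composite, 6),
    )
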