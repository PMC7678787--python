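"""Interactome size estimation and reliability arithmetic.

The predicted-association count decomposes into true interactions the
model recovers and false positives among the non-interacting pairs:

    N_interactome * sensitivity
        + (N_all_pairs - N_interactome) * (1 - specificity) = N_predict

Solving for ``N_interactome`` gives the expected number of true
interactions in the species; multiplying by sensitivity gives the
expected number of true interactions among the predictions, and
dividing that by ``N_predict`` gives the reliability (the fraction of
predicted associations expected to be real).  Coverage equals the
sensitivity.  The equation is identifiable only when
``sensitivity > 1 - specificity`` (the classifier beats chance).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SizeEstimate:
    n_interactome: float
    n_all_pairs: float
    n_predict: float
    sensitivity: float
    specificity: float

    @property
    def expected_true_in_predictions(self) -> float:
        return self.n_interactome * self.sensitivity

    @property
    def reliability(self) -> float:
        return self.expected_true_in_predictions / self.n_predict

    @property
    def coverage(self) -> float:
        return self.sensitivity


def conservative_sensitivity(*sensitivities: float) -> float:
    """The smaller of several sensitivity estimates (training vs
    validation stage): the conservative choice for size estimation."""
    if not sensitivities:
        raise ValueError("need at least one sensitivity estimate")
    return min(sensitivities)


def estimate_interactome_size(
    n_predict: float,
    sensitivity: float,
    specificity: float,
    n_all_pairs: float,
) -> SizeEstimate:
    """Closed-form solution of the size equation.

    Raises when the equation is unsolvable (``sensitivity <= 1 -
    specificity``) or the solution falls outside ``(0, n_all_pairs)``.
    """
    if not 0.0 <= sensitivity <= 1.0 or not 0.0 <= specificity <= 1.0:
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if n_predict < 0 or n_predict > n_all_pairs:
        raise ValueError("n_predict must lie in [0, n_all_pairs]")
    fpr = 1.0 - specificity
    denom = sensitivity - fpr
    if denom <= 0:
        raise ValueError(
            "equation unsolvable: sensitivity must exceed the false positive "
            f"rate (got sensitivity={sensitivity}, 1-specificity={fpr})"
        )
    n_int = (n_predict - n_all_pairs * fpr) / denom
    if n_int <= 0:
        raise ValueError(
            f"negative interactome size ({n_int:.4g}): the predicted count "
            "is below the expected false-positive count alone"
        )
    if n_int >= n_all_pairs:
        raise ValueError(f"estimated size {n_int:.4g} exceeds the pair universe")
    return SizeEstimate(
        n_interactome=n_int,
        n_all_pairs=float(n_all_pairs),
        n_predict=float(n_predict),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
    )


def reliability_report(est: SizeEstimate) -> str:
    """Human-readable coverage/reliability summary (full precision kept
    internally; display rounded)."""
    lines = [
        "Interactome size estimate",
        "-------------------------",
        f"predicted associations      : {est.n_predict:,.0f}",
        f"pair universe               : {est.n_all_pairs:,.0f}",
        f"sensitivity (coverage)      : {100 * est.coverage:.2f}%",
        f"specificity                 : {100 * est.specificity:.2f}%",
        f"estimated interactome size  : {est.n_interactome:,.0f}",
        f"expected true predictions   : {est.expected_true_in_predictions:,.0f}",
        f"reliability                 : {100 * est.reliability:.2f}%",
    ]
    return "\n".join(lines)
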