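"""Aligned-text and JSON rendering of fit results and robustness tables."""

from __future__ import annotations

import numpy as np

from .coding import ComparisonTable
from .estimation import FitResult, HYPOTHESIS_TERMS, hypothesis_verdicts, wald_report
from .network import TOPIC_LABELS

#: display names for the reply-network model terms
TERM_LABELS = {
    "edges": "edges (density)",
    "mutual": "reciprocity",
    "nodematch.gender": "gender",
    "nodeifactor.experience.1": "user_registration_time",
    "nodemix.emotion_polarity.2.2": "positive_positive",
    "nodemix.emotion_polarity.1.1": "negative_negative",
    "nodemix.emotion_polarity.2.1": "positive_negative",
    "nodemix.emotion_polarity.1.2": "negative_positive",
}
TERM_LABELS.update(
    {f"nodematch.topic_preference.{l}": f"topic_type_{TOPIC_LABELS[l]}" for l in TOPIC_LABELS}
)

_TERM_HYPOTHESIS = {}
for h, terms in HYPOTHESIS_TERMS.items():
    for t in terms:
        _TERM_HYPOTHESIS[t] = h
_TERM_HYPOTHESIS["nodemix.emotion_polarity.1.1"] = "H5"
_TERM_HYPOTHESIS["nodemix.emotion_polarity.1.2"] = "H5"


def term_label(name: str) -> str:
    return TERM_LABELS.get(name, name)


def render_fit_report(fit: FitResult, verdicts: dict | None = None) -> str:
    """Aligned coefficient table: Hypothesis | Parameter | Estimate | S.D. |
    p | stars | Result.  p-values print at 3 decimals (p < 0.0005 renders as
    0.000); the JSON twin (``FitResult.to_json``) keeps full precision."""
    table = wald_report(fit)
    if verdicts is None:
        try:
            verdicts = hypothesis_verdicts(fit)
        except Exception:
            verdicts = {}
    rows = []
    seen_h = set()
    for _, row in table.iterrows():
        h = _TERM_HYPOTHESIS.get(row["term"], "")
        result = ""
        if h and h in verdicts and h not in seen_h:
            result = verdicts[h]
            seen_h.add(h)
        rows.append(
            (
                h,
                term_label(row["term"]),
                f"{row['estimate']:.3f}",
                f"{row['std_error']:.3f}",
                row["p_text"] if row["defined"] else "undef.",
                row["stars"],
                result,
            )
        )
    header = ("Hypothesis", "Parameter", "Estimate", "S.D.", "p", "", "Result")
    widths = [max(len(str(r[c])) for r in rows + [header]) for c in range(len(header))]
    lines = [
        f"Fitted by {fit.method}; converged={fit.converged}; "
        f"two-sided Wald p-values; * p<0.05 ** p<0.01 *** p<0.001"
    ]
    lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)).rstrip())
    lines.append("-" * (sum(widths) + 2 * (len(widths) - 1)))
    for r in rows:
        lines.append("  ".join(str(v).ljust(w) for v, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"


def render_comparison(comparison: ComparisonTable) -> str:
    """Aligned robustness table: one column of estimates + stars per model."""
    models = list(comparison.models)
    rows = []
    for term in comparison.terms():
        cells = []
        for m in models:
            v = comparison.estimates.loc[term, m]
            if not np.isfinite(v):
                cells.append("failed" if not comparison.converged.get(m, True) else "")
            else:
                cells.append(f"{v:.3f} {comparison.stars.loc[term, m]}".rstrip())
        rows.append([term_label(term)] + cells)
    header = ["Parameter"] + models
    widths = [max(len(str(r[c])) for r in rows + [header]) for c in range(len(header))]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths)).rstrip()]
    lines.append("-" * (sum(widths) + 2 * (len(widths) - 1)))
    for r in rows:
        lines.append("  ".join(str(v).ljust(w) for v, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"
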