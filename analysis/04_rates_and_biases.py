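#!/usr/bin/env python
"""Estimate per-generation event rates and test the direction biases.

Rates: events / (generations x 2 x arm length), using the calibrated
generation span from the tree stage. Biases: chi-square (1 df, no
continuity correction) on conversion polarity, conversion GC direction and
mutation GC direction (all and private-only), plus the descriptive
GC-neutral conversion polarity subtable.

Reads results/sim/, results/tree/, results/events/; writes results/rates/.
"""

import json
from collections import Counter
from pathlib import Path

import pandas as pd

import ygc
from ygc import io as yio

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "rates"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = yio.read_config(BASE / "sim" / "sim.cfg")
    events = yio.read_events_tsv(BASE / "events" / "events.tsv")
    cal = json.loads((BASE / "tree" / "calibration.json").read_text())
    generations = cal["generations_estimate"]
    length_bp = 2 * params.arm_length_bp

    kinds = Counter(e.kind for e in events)
    rates = {}
    for kind in ("mutation", "conversion"):
        est = ygc.estimate_rate(kinds[kind], generations, length_bp)
        rates[kind] = {
            "n_events": est.n_events,
            "generations": est.generations,
            "length_bp": est.length_bp,
            "rate_pppg": est.rounded(3),
            "true_rate_pppg": params.mu_pal if kind == "mutation" else params.gamma,
        }
    (OUT / "rates.json").write_text(json.dumps(rates, indent=2) + "\n")

    report = ygc.summarize_biases(events)
    df = pd.DataFrame(
        [
            {
                "section": s["section"],
                "label_a": s["labels"][0], "n_a": s["counts"][0],
                "label_b": s["labels"][1], "n_b": s["counts"][1],
                "pct_a": s["percent"][0], "pct_b": s["percent"][1],
                "chi2": s["statistic"], "p_value": s["p_value"],
            }
            for s in report
        ]
    )
    df.to_csv(OUT / "bias_report.tsv", sep="\t", index=False)

    for kind in ("mutation", "conversion"):
        r = rates[kind]
        print(f"{kind} rate: {r['rate_pppg']:.3g} PPPG "
              f"({r['n_events']} events; generating rate "
              f"{r['true_rate_pppg']:.3g})")
    for s in report:
        a, b = s["counts"]
        p = s["p_value"]
        print(f"{s['section']}: {s['labels'][0]}={a} vs {s['labels'][1]}={b} "
              f"({s['percent'][0]}% vs {s['percent'][1]}%)"
              + (f", p={p:.3g}" if p is not None else ""))
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
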