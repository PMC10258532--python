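"""Distance-matched thresholds vs a uniform cutoff on planted bundles.

Runs the end-to-end recovery experiment: a synthetic cohort with 20
planted long-range bundles (>= 80 mm) is thresholded with the
distance-dependent nulls at alpha = 0.1, and with a distance-blind
uniform cutoff matched to the same number of surviving edges.  The
uniform cutoff, dominated by strong short-range scores, deletes the
long-range bundles that the distance-matched thresholds keep.
"""

import json

from dddthresh import GeneratorConfig, run_recovery_replicate

res = run_recovery_replicate(GeneratorConfig(seed=0), alpha=0.1)
print(json.dumps(res, indent=2))
print(
    f"\nlong-range sensitivity: DDD {res['ddd']['long_sensitivity']:.2f} "
    f"vs uniform cutoff {res['baseline']['long_sensitivity']:.2f} "
    f"(both keep {res['n_surviving_ddd']} edges)"
)
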