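"""Relative SNR, relative CNR and COV of the dark vs bright arms.

Both relative metrics normalize each arm by the SD of its background air, so
they isolate the preparation penalty of the DIR pulses: values below 100%
mean the dark arm is noisier relative to its signal.  The COV of remote
myocardium rises in the dark arm because the preparation scales the tissue
signal down while thermal noise is unchanged.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_study


def main() -> None:
    sig = ensure_study()["summary_signal"]
    cols = ["field", "phase", "relative_snr_mean", "relative_snr_sd",
            "relative_cnr_mean", "relative_cnr_sd", "cov_increase_pct_mean"]
    print("\nPaired signal metrics per cell:")
    print(sig[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    s15 = sig.loc[sig["field"] == "1.5T", "relative_snr_mean"].mean()
    s3 = sig.loc[sig["field"] == "3T", "relative_snr_mean"].mean()
    print(f"\nRelative SNR < 100% everywhere; mean {s15:.1f}% at 1.5T vs {s3:.1f}% at 3T —")
    print("the dark-blood penalty is larger at 3T (longer adiabatic pulses,")
    print("lower lumped inversion efficiency in the preset).")


if __name__ == "__main__":
    main()
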