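"""Generate the synthetic imaging session used by the downstream analyses.

Emulates one anesthetized-mouse recording: per odorant (ethyl butyrate,
methyl valerate), 3 control trials then 9 odor trials (0.3/1/3% saturated
vapor pressure, 3 repetitions each), recorded in both the 590 nm
blood-volume channel (7 Hz) and the GCaMP6f calcium channel (25 Hz).
Writes the trial TIFF stacks, the session manifest and the ground truth to
results/session/.  Image size is reduced to 64x64 to keep the artifact
small; the forward model is resolution-independent.
"""

from pathlib import Path

from obnvc.session import write_session
from obnvc.synth import SessionConfig, synthesize_session

OUT = Path(__file__).resolve().parent.parent / "results" / "session"
SEED = 20260926


def main() -> None:
    config = SessionConfig(height=64, width=64, dtype="float32")
    movies, truth = synthesize_session(config, seed=SEED)
    write_session(movies, OUT, truth)
    n_bv = sum(m.channel.value == "BV590" for m in movies)
    print(f"wrote {len(movies)} trial stacks ({n_bv} BV) to {OUT}")
    print(f"true transfer function: {truth.true_hrf}")
    print(f"vessel mask pixels: L={truth.vessel_masks['LEFT'].sum()}, "
          f"R={truth.vessel_masks['RIGHT'].sum()}")


if __name__ == "__main__":
    main()
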