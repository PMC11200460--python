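"""Extract per-window band-power features and report the sample counts.

Each 60-s Hamming window yields a six-dimensional vector (delta/theta/gamma
amplitude and spectral ratio) per observed region; counts per mouse follow
the sessions x windows design.
"""
import pandas as pd

from analysis_config import RUN_DIR, ensure_run


def main() -> None:
    ensure_run()
    table = pd.read_csv(RUN_DIR / "features.tsv", sep="\t")
    per_mouse = table.groupby("mouse")[["session", "window"]].apply(
        lambda f: len(f.drop_duplicates()))
    windows = table.groupby(["mouse", "session", "region"]).size()
    print(f"feature rows: {len(table)} "
          f"({table['mouse'].nunique()} mice x sessions x windows x regions)")
    print(f"windows per (mouse, session, region): {sorted(set(windows))}")
    print(f"window units per mouse: {sorted(set(per_mouse))}")


if __name__ == "__main__":
    main()
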