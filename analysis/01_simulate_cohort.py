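"""Generate the demo cohort and summarize its structure.

Writes the missingness mask and labels to results/ and reports how many
(mouse, region) cells the equipment-failure model removed.
"""
import shutil

from analysis_config import RESULTS, RUN_DIR, ensure_run


def main() -> None:
    manifest = ensure_run()
    sim = manifest["stages"]["simulate"]
    print(f"cohort: {sim['n_mice']} mice, "
          f"{sim['masked_cells']} of 225 (mouse, region) cells missing "
          f"({100 * sim['masked_cells'] / 225:.1f}%)")
    for name in ("mask.tsv", "labels.tsv"):
        shutil.copy(RUN_DIR / name, RESULTS / name)
        print(f"wrote results/{name}")


if __name__ == "__main__":
    main()
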