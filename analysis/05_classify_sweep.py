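"""Leave-mouse-out classification over top-R region subsets.

For R = 1..9, the projections of the R top-ranked regions feed four
classifiers (LDA, KNN, linear SVM, ELM); every fold holds out all windows
of one mouse.  Writes the accuracy-vs-R summary and per-mouse evaluation
grid to results/.
"""
import json
import shutil

from analysis_config import RESULTS, RUN_DIR, ensure_run


def main() -> None:
    manifest = ensure_run()
    summary = manifest["summary"]["per_classifier"]
    print("mean leave-mouse-out accuracy vs R:")
    header = "classifier " + " ".join(f"R={r}" for r in range(1, 10))
    print(header)
    for kind, entry in summary.items():
        curve = {int(k): v for k, v in entry["accuracy_vs_R"].items()}
        row = " ".join(f"{curve[r]:.3f}" for r in range(1, 10))
        print(f"{kind:>10} {row}  (best {entry['best_accuracy']:.3f} "
              f"at R={entry['argmax_R']})")
    shutil.copy(RUN_DIR / "evaluation.tsv", RESULTS / "evaluation.tsv")
    (RESULTS / "classification_summary.json").write_text(
        json.dumps(manifest["summary"], indent=1))
    print("wrote results/evaluation.tsv and results/classification_summary.json")


if __name__ == "__main__":
    main()
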