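# Reduced-scale end-to-end demo of the synthetic study (a few minutes on one CPU)
demo:
	isocall run --out scratch/demo --seed 1

test:
	python -m pytest -q tests/

.PHONY: demo test
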