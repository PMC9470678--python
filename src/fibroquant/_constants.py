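"""Shared tissue-class codes for the five-class labeling scheme."""

CLASS_NAMES = ("air", "muscle_water", "fat", "skin", "fibrosis")
AIR, MUSCLE_WATER, FAT, SKIN, FIBROSIS = range(5)
N_CLASSES = 5

AIR_HU = -1000.0
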