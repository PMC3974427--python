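species	form_label	apex	apical_spire	basal_spire	parietal_teeth	basal_teeth	tuba_form	aperture_view	peristome	spiral_lines	rib_shape	rib_thickness
Plectostoma salpidomon		1	2	2	2	2	2	2	2	2	2	2
Plectostoma laemodes		1	2	2	2	2	2	2	2	2	2	2
Plectostoma dindingensis		2	2	2	4	2	1	3	2	1	3	2
Plectostoma mengaburensis		2	2	2	4	2	1	3	2	1	3	2
Plectostoma ikanensis	Form BOR 5504	2	2	1	4	2	2	1	2	1	3	2
Plectostoma ikanensis	Form BOR 5507	2	2	1	4	2	2	1	2	1	3	2
Plectostoma annandalei		1	2	1	?	?	2	2	2	?	3	?
Plectostoma kayiani		2 or 3	2	1	4	2	2	1	2	2	1	2
Plectostoma charasense		1	1	1	2	1	2	2	2	2	2	1
Plectostoma christae		2	2	2	2	2	1	4	2	2	3	2
Plectostoma crassipupa		2 or 3	2	2	4	2	3	4	2	1	3	2
Plectostoma davisoni		2 or 3	2	2	2	2	2	1	2	1	3	2
Plectostoma kakiense		2 or 3	2	2	2	2	2	2	2	2	3	2
Plectostoma kitteli		1	1	1	2	2	2	2	2	2	2	2
Plectostoma klongsangensis		1	1	1	?	?	2	2	2	1	1	1
Plectostoma kubuensis		2 or 3	2	2	4	2	2	2	2	2	3	2
Plectostoma laidlawi		1 or 2	2	1	2	2	2	2	2	1	3	2
Plectostoma palinhelix		3	2	2	2	2	2	3	2	1	3	2
Plectostoma panhai		2	2	2	3	2	1	3	2	1	3	2
Plectostoma praeco		1	2	1	2	2	2	2	2	2	2	2
Plectostoma relauensis		2 or 3	2	2	3	2	2	1	2	1	3	2
Plectostoma retrovertens		2	2	2	2	2	2	3	2	1	3	2
Plectostoma sciaphilum		1	1	2	2	2	3	4	2	1	2	2
Plectostoma senex		1	1	2	2	1	3	4	2	2	2	2
Plectostoma sinyumensis		2	2	3	4	2	1	3	2	2	3	2
Plectostoma siphonostomum		1	1	1	2	2	1	4	2	1	3	2
Plectostoma tenggekensis		2	2	1	2	2	2	2	2	2	1	2
Plectostoma tohchinyawi		1	1	1	2	2	2	2	2	1	1	1
Plectostoma tonkinianum		1	2	2	1	2	3	1	1	2	2	2
Plectostoma turriforme		1	1	2	1	1	3	4	2	2	2	2
Plectostoma umbilicatum		2	1	2	4	2	1	3	2	1	3	2
Plectostoma whitteni		1	2	2	4	2	3	1	2	2	3	2
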