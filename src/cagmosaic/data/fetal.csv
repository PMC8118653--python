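id,cag_fetal_brain,ei_fetal_brain,cag_trophoblast,ei_trophoblast,cag_parent_blood,ei_parent_blood
1,40,0.0441,40,0.0407,40,0.1255
2,41,0.0494,41,0.0495,40,0.1073
3,42,0.0434,42,0.0473,42,0.2383
4,43,0.0489,43,0.0482,45,0.3434
5,45,0.0533,45,0.0516,45,0.3692
6,46,0.0523,46,0.0571,45,0.3692
7,46,0.0599,46,0.0589,45,0.2390
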