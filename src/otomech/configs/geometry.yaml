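# Middle-ear geometry, SI units (metres; fractions dimensionless)
aml_length: 0.0018
aml_radius: 0.00034
annular_ring_width: 0.0006
attic_patch_fraction: 0.0625
footplate_height: 0.0018
footplate_thickness: 0.0006
footplate_width: 0.003
im_joint_length: 0.0006
incus_length: 0.0048
incus_process_width: 0.0012
is_joint_length: 0.0006
malleus_length: 0.0048
mesh_resolution: 0.0003
ossicle_width: 0.0012
pil_length: 0.0018
pil_radius: 0.00034
stapedius_length: 0.0018
stapedius_radius: 0.00034
stapes_length: 0.0024
stapes_offset: 0.0
tensor_tympani_length: 0.0018
tensor_tympani_radius: 0.00034
tm_depth: 0.0012
tm_radius: 0.0032
tm_thickness: 0.0006
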