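human_mirna_id	family	bta	gga	ssc	eca	cfa	total_animal_species
hsa-miR-128-3p	mir-128	+	+	+	+	+	5
hsa-miR-130a-3p	mir-130	+	+	+	+	+	5
hsa-miR-135a-5p	mir-135	+	+	+	+	+	5
hsa-miR-148a-3p	mir-148	+	+	+	+	+	5
hsa-miR-184	mir-184	+	+	+	+	+	5
hsa-miR-19a-3p	mir-19	+	+	+	+	+	5
hsa-miR-193a-5p	mir-193	+	+	+	+	+	5
hsa-miR-204-5p	mir-204	+	+	+	+	+	5
hsa-miR-205-5p	mir-205	+	+	+	+	+	5
hsa-miR-27b-3p	mir-27	+	+	+	+	+	5
hsa-miR-29b-3p	mir-29	+	+	+	+	+	5
hsa-miR-30b-5p	mir-30	+	+	+	+	+	5
hsa-miR-365b-3p	mir-365	+	+	+	+	+	5
hsa-miR-490-3p	mir-490	+	+	+	+	+	5
hsa-miR-19b-3p	mir-19	+	+	+	+	-	4
hsa-miR-193a-3p	mir-193	+	+	+	+	-	4
hsa-miR-24-3p	mir-24	+	+	+	+	-	4
hsa-miR-206	mir-1	+	+	-	+	+	4
hsa-miR-20a-5p	mir-17	+	+	-	+	+	4
hsa-miR-190a-5p	mir-190	+	+	-	+	+	4
hsa-miR-194-5p	mir-194	+	+	-	+	+	4
hsa-miR-216b-5p	mir-216	+	+	-	+	+	4
hsa-miR-383-5p	mir-383	+	+	-	+	+	4
hsa-miR-98-5p	let-7	+	-	+	+	+	4
hsa-miR-99b-5p	mir-10	+	-	+	+	+	4
hsa-miR-130b-3p	mir-130	+	-	+	+	+	4
hsa-miR-148b-3p	mir-148	+	-	+	+	+	4
hsa-miR-149-5p	mir-149	+	-	+	+	+	4
hsa-miR-187-3p	mir-187	+	-	+	+	+	4
hsa-miR-532-5p	mir-188	+	-	+	+	+	4
hsa-miR-196a-5p	mir-196	+	-	+	+	+	4
hsa-miR-208b-3p	mir-208	+	-	+	+	+	4
hsa-miR-92a-3p	mir-25	+	-	+	+	+	4
hsa-miR-92b-3p	mir-25	+	-	+	+	+	4
hsa-miR-26a-5p	mir-26	+	-	+	+	+	4
hsa-miR-151a-5p	mir-28	+	-	+	+	+	4
hsa-miR-29c-3p	mir-29	+	-	+	+	+	4
hsa-miR-324-5p	mir-324	+	-	+	+	+	4
hsa-miR-328-3p	mir-328	+	-	+	+	+	4
hsa-miR-331-3p	mir-331	+	-	+	+	+	4
hsa-miR-34a-5p	mir-34	+	-	+	+	+	4
hsa-miR-361-5p	mir-361	+	-	+	+	+	4
hsa-miR-376a-3p	mir-368	+	-	+	+	+	4
hsa-miR-370-3p	mir-370	+	-	+	+	+	4
hsa-miR-374b-5p	mir-374	+	-	+	+	+	4
hsa-miR-423-5p	mir-423	+	-	+	+	+	4
hsa-miR-499a-5p	mir-499	+	-	+	+	+	4
hsa-miR-628-5p	mir-628	+	-	+	+	+	4
hsa-miR-708-5p	mir-708	+	-	+	+	+	4
hsa-miR-885-5p	mir-885	+	-	+	+	+	4
hsa-miR-146a-5p	mir-146	-	+	+	+	+	4
hsa-miR-21-5p	mir-21	-	+	+	+	+	4
hsa-miR-218-5p	mir-218	-	+	+	+	+	4
hsa-miR-22-3p	mir-22	-	+	+	+	+	4
hsa-miR-34c-5p	mir-34	-	+	+	+	+	4
hsa-miR-9-5p	mir-9	-	+	+	+	+	4
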