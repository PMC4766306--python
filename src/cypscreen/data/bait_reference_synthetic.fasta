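>N4OMT_reference_synthetic synthetic bait-gene (O-methyltransferase-like) reference peptide
MQVAWNDLQFTTGECDMFRGWETNGNSWFPIECHNKSAGLNRRPYWCEPENHAVCMPIHG
FLGCNVHKLSIHTIQGEVMCMPIGHDDARWTRNGTSHYEIWPDAGWGTCGEYLNMTMQSW
RIIYCIYHFPDDDMWKTIAYPMWLIHQLWKNVHQIGNMLVHEFYMMEPTTNDYHFPITCG
CLGTMFRNAPKVVHVRNWHSEEEHKSVTWHPRAYDLKFDYAPVHRCHWCAFETMEPSCCW
PCPDCWQRSHQWLCDNPQCWGMREKPNPKCCCMWPIQLENWPKGSHCCGPWESDEKHEFL
FLCRTIPMDPTYKDEIVGLLQVPRYCPRHYLVCKTDSTYWVRKAGATMWTIWHMQVWPLY
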