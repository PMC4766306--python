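>P450_template_synthetic synthetic cytochrome P450-like template peptide
MGEQHCQFGSITGREFSCSQHPTQSALDLGSLIECPRMMWTGWLKEAPRHGSQYEVHYPH
VPLYIMGCGMCYGNCIDMLYTMAANHNASMYDESMFMQTQKDLAWRHYRCGQQKRHTGYP
QWENWKHTRMDHWELFNTEAMNWSIFYRLSMLGCPVKHDSKIDVSLEHTQDCDFIYADWR
PVNNFKISFWFQQRKWANDPQHVSDFSTEADYPYVWLSQIPHQPKRNHAIMPDRFIFSFN
CWFQPHLCVMYGDFWDCCYWFWKEDHFWDGYFESFEEREVKTAGMFCSRIVLTVVLAVCG
HMFKKRMTLIFGQNYPVPRAGNETTHKQKKVPGEVIIAVAVVVECIQFSIEVFQHWSTLL
IHVDEVGEWRKMPWISHMGKLSCPVIETLRNRNMDRNEYYQVYHEIMLSPYSVGYISKRS
QRKMCWEWDPERFVPKNNVPAGKYNGEPLLICTGNIMKSSWVMFSAGSRNCIGKMLEEWS
KEHQYRLWQAACEQMNQKCQ
>P450_ref_synthetic_01 synthetic reference P450, 0.90 identity to template
MGEEHCQFGSGTGREFSCSWHPVQSALDLGSLIECPRMMWTGWLKEAPRHGSQYEVHYGH
VPFYIMGCGMCYGNTIDMLYTMAINHNASMYDESMFMQTQKDLAWRHIRCGQQKRHTGYI
QWENWKHTRMDHWELFNTEAMNWSINYRLSMLGCPVKHDSKIDVSLEHTQMCDFIYADWR
PVNNFKISFWFQQRKWAVDPQDESDFSTEADYPYVWLSMIPHQPKRNHAIHPHQTLFSPN
CWFQPHECVMYMDAWDCCYWFWKEDHFWDIYFESFEYREPKTAGYFCSRIVLTVVLAVDG
HMFKKRMTLIFGQNYPKPRAGNETTHKQMKVYGERICAVAVVVECIQFVIEVFQHWSTLL
IHVDYVGEWRKMPWISHMGKLSCPMIETLRNRVNDLHELYQVYHEIMLSPYSVGYISKRS
QRKMRWEWDPERFVPKNNVPAGKYNGEPLKICTGNIMKSSWVMFSAGSRNCIGKMLEEMI
KEHQVRLWQAACFTMNQKCQ
>P450_ref_synthetic_02 synthetic reference P450, 0.85 identity to template
MGEQHCQFGSITGRGFSCSQHCTQSALDLGSIIECPRMMLTFWIKEAPPHGYQYEVHPPH
VYLYISCCVYCYGNCIDMLYTMAANHNDSMYDRSMPMQTQKDLAWRHYRVLQQKRHTGYP
QWEAWKFTRMEHSMLFNTEAMNWSIFYRRSMLGCPVKHDFKWCVSLFHTQDCDWIYADWR
PRNNTKISIWTQQRKWANDPQHVSDFSTEADIMYVWQGYIPHQPKRGHAIMPDRFIFSFN
AWFQPHLCVMYGCSWDCCYWFWKEDHFWDGYIQSFNEKEVKTAGMFCSRIDLTLVIAGCG
HDPKKRMELIFGQNYPWPRAGNETTHKQKKSPGMVIIAVAVVVECIQFSIEVFQKWSYLL
IHVREVGEWRKMPWISLTSKLSCPVIETLRPENQDRNEYYQVYAEIMLSPYSVGYISKRS
QRYDCWEWDPERFLPKNNVPAGKPNGEPLLICTGNIMKSSWLMFSAGSRNCIGKMLEEWS
KEQQYRLWQAACQQQNQKCQ
>P450_ref_synthetic_03 synthetic reference P450, 0.80 identity to template
MGEQHCQFGSITGREWSCSQHVTQSAEYQKSNIEQPQMMWTWWRKSQPYHGSQYECHYSY
VPLYIMGCGMKYGNCIDMLYTMAWNHNASMYDESMFMQTQMRLKWRHYRCGQQKRHSWHP
WAENWKHTTMDHWELFNTEAKNWSIFYRLSMLRNEHKHDSKIDVSLEHLQDCDFIYADWR
PVNNRKIEFWWMQRKWANDPQHVSDFSTEADTPYVWLQQIDCQKKRNIAIWPARFIFSVL
DRFQNHLYVPYGDFWDCCYWFWKIDHFWDGYFESFEEREVKTAGMSCSRIVQTVVLAVCG
HMFKKRMTLIFGYNYLYPWAGNETTHKQHKVPIEVNIAVAVVVECIMFSALMYQHWVGYL
IHVQEGGEWPKQEWISHMGKDDCPMIETLRNRYFTRNFYYQVYHPIMYSPYSVGYIIKRS
ERKPCWEWDPERFVPPNNVPAGKHIGEPLLICTGNIMKSGLVMFSAGSRNCIGKMLEEWS
KEYQTRLCQAPCKQQNQKCC
>P450_ref_synthetic_04 synthetic reference P450, 0.75 identity to template
MGEQERQFGCITGREFSCSHHPTQSALDLESYIECPAMWATPEPKSAPGHSSIYEVTSSN
TPLYIMGCGMCYGNCIDMNYTMFANHTPSMYDERMKMQPQKSLAWLHQRCGQQKRHTGYF
QWENPKHEMMDHWELFNTEAMNWSIFYRNSSLGCVVKHDSIIDVSLIHNQDCDFISWDQF
PVFNFKISGWFQQHKWSDDPQHVCKFSTEADYPIVWLSQDPHHPYREHAWHPDRFKCDVY
CWCGPHAIVEYGDQWDTCYWRWKEDHFWDSYEESFSEMEWKEAHMGCSRHVLTVVLAFCW
HRFSKRHFLIFGQNYPVDRAGNETTHPHKKQCGEVHIAVHVVVETFQFSYEVEQISSTLQ
GHWDEVGDWRKMPWIQHRQKLSCPVIETLRNRNSNRNEVYFVAHEIMLSPFSVGYISKRQ
IRKMCWEWDPERFVPKMNVPAGKLNGEPVDICDGNIMKSSWVMFSAGSRNCIGKALEEWS
KEINYRLWQAACEQMYQKCD
>P450_ref_synthetic_05 synthetic reference P450, 0.70 identity to template
MLEQHCIFGVITGREIGQSQHKTQSALFGGSLDECPMSMWTGWLMKPDNHGSNYEVHHPH
YCLYIMGCGMCYRHCIDMLFTMAAMHNASDYDENMFMPTCKDFHSRFYRTGSLKRHTGYP
LWEAWKHTWMDHWVRHNTSSGVWLIGYISSKPGCIVNIDQKIYVSLESTQDCDRIYADWR
PVNNTKICSWFPQQKEARDPQAVYDFYTDIYNPWVWLSQDPCEPKRNHAIHPDRFIFSFY
ICQLPHLCVLYQMSWDCCYQFFFEDHFWDGYFESFEEREIKTAGVFCSRIVLTVALAVTA
HMFKWRMTGTFGCNHYPPCAGNETTIKIKKKNGEVIINVPVFVECKQLSIEVYQHWSTLL
MHVYFNMEWRKEPWGSHMGYLWCMVIETLRNYNMVRHEYYQVKIEISLDPNPVGYISKRS
WRLMCWIFDPERFVPKTNVPAGKYNKEPQLNITGNDMRLFKVMFSAGSRNCIGKMLEEWS
KEHQYRTGQPICEQMNQKCQ
>P450_ref_synthetic_06 synthetic reference P450, 0.65 identity to template
MMHEHCQFISLNGREHSGVQRNNLSALDLGSNVEVPPKVWTWILKEALRHGWQYAWMIPH
VVFYIWGCCMCAGNCGDWHYTMIALHAWSMYWESMFSPTDKDLAWRHYRCYYQCYFSGYP
LWPNKKHMRHDGWTLDNTEHRNWSIFYRLSTLRHPVDSDSHIDVCSFRVQDDMFINADWR
PYNNNKISFFFPQRKAWNDPQHVVTPSTCQTYPYVWWTQIPHCPKRNEFIFPRRFFFDFE
MWFQPHLCVMYGDFQDGCCKMIKEDHVWDGYTESFEERHNPTQWMCCSRWVLKFYQAVCN
HMFSERMTLINGNNYPIDRAGNETTHKHMKVSTEVIMAVAVIVLCIQFSQDEFQHWSTLK
SHVDEVGEWFKCPWISHIGKLIKPVFETLRYYNEDTNEYYHVYHEQMLYSYDVGYISKRN
IRKPCWEWWPERFVPFNFVPAGKYNGEPLHIMFMNYMKSSWTMFSAGSRNCIGKGQRIHS
KMQQMRPWQAAYEAMFFKCM
>P450_ref_synthetic_07 synthetic reference P450, 0.60 identity to template
MGEVHCHFGSITGVRFSFMVIPEQLALEPGHLIELPDMPNTDHGKESMRQPWLHLIWDPL
VTRVFHDVHNCYGDAINMLKTMPAKLHASMYREPHFMERQKDLAVRGYREQQCKRHGCIP
QWEDIPHRRTCHWELKNEEVNNWIIFMRLSMVGHDVKHDNKIDGSAEINQCWDGFYAAWM
RYNNFKISPEFQPREWANVPLIVSKFGKEAIYSGVWLYCIDFQPCRNHAFMPDRFILSTG
HCKQPDLCVMYGPFWDCCIWFCKEDRFWAGYQESFEERVGKTQGMFKSTAVLGMWLSVSG
HMFKQRMTLITGQHYPQPRAGNETTHSCKKVPGEVIPAPDVVVERIMFVFEPFGWMDTLR
ILVDAARQRRNMPDGSHCGCLPCLQFETLRNRAHDENNYVQVYHVIMLKVYSRIYISFRF
FHLMCMFPYPERFLPKGQVPAGKYCFEFLRICTGNIMKSSWVMFSAGSRNCIGKMARTWR
KECQYRLWRAACEQMTQKCQ
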