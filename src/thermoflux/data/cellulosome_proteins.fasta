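>CipA synthetic cellulosomal protein (540 aa)
TTDVGLIFFGPQFSVCSEAIATNAKILYNYSADMSGKPYGFEYHIVTVVFKEKNDMRESP
KLPVVKKDYKVATNNKEASKVKGFKSHRIMFNADRNIVNEDEQAKCVIQEQRTGNEREMR
IITGHVIRASVYNGTADLRDRTAASTKPTGINKDLTAVSVETDSLTKLMFFQGDLHSTIL
SLGHSLKLNNKDERDASAVFFKLKNEVVVHLVTVSDYEIKLTFLSEVIGVVEVDWGEDFG
AHNGKKGPRNKPLFDPFTGWEDTESWLVGRTDTGPLGANLRTANFGITFVKGAHGDQAAL
GTVAGTRSHVTLEFQTYPIDDHAAAYKKVVKTPVQFQKGIHNEYDNLTSALIVLGLVRAN
RAVTLLTLSKLNVGYQGAADCAQGIVARFRQFVAIHKVTEGVLHNSLWVLAVIYSLILRV
LDGTFGLALTEVTPPIDGLDFTNIVGGYSHLYYRHTTTFHDHDKYLRNWGSFIADSYAKV
VSKGNAGVILIVANVANDLGGNDNYLWDSVEWIVIETIAPGVKTVLGISSPSSTTKIEEE
>CelS synthetic cellulosomal protein (420 aa)
EGAETRTESGPDEGQSLPFTGTILNAGAMGKGEWSHKRRWLPSVLLSGVGSTDAKEGGCS
QANFLENFLQVLQAKKDAYRYNYEDSIVFFGNIGSTWHGVLDEDGEAALGYSAGVNKGSP
QTMDIWQSWDNDNVYADYRGLELDDVNIPQFGPDNYNGEMIHRNKVARDGSTGYINAVKV
GVPSDRERADGLLMELLTQESGDALDYNPTFKLSDYNASTWVGNIFHMKEFVCFSLSYTA
KIVGEVADWEPVSLKNEPELKGYDTYDALTHTGVGKRDDKVGKKQMPQAGKSPTLPWFYQ
RKILGVLLNPAQARIYWLAPTTDTYEETTRSSASNCKYALGQVGCCSSGGIPGPKMRALA
FSPNAAQSVATVPKKHLEKQDGDWPTAFVGSDNFYYIYLTDVVKAISAHHTTPVGNSGQS
>CelK synthetic cellulosomal protein (380 aa)
FALFRLGKGMSGDEANYVRNIAAVEIVVARKNSPQEAVHNHSEEVGIVGDAGRQKSELDK
ADIRTKTSISCEGILFDDGYSAVTGITDNWNRNCGKLEICFLHSIGKFGEWIQSDVNLAI
SYVSDSDANNGKYQRFSTACVMVRVDHFGLISTYPLNNKVLCCGWDVRENNSSLEMKQTK
QGCQGMTVFPPETAEYYTRYALMGVRLDAQKAYVNTGNATISLGMLVCLMGQANYSAANA
STEEMVKAGVQYSVIEGGFLILQLNADLYGIQVHTLDGDRDITTNTKTRIEGQSTENIFL
KLQYQLVAPPQYPTTFQTVIRAFPFDDISQQETYRAPNLGTGLYLIRSLDAPILVLRQNL
VHLVKKILASPDEYRSAVLG
>CbhA synthetic cellulosomal protein (360 aa)
DKPTVNVEGAEMPNSVRIVFVGVRKGMGIDEVYAALLLRAKDFWTPITNARAPIALKRTR
SNQTNSEDEPYFFGGTVVSFKDLVTYSAWSYYTADALTAKKKLSAYQHMLAVRFSRPLII
RLGLDISNVTCVTVCRTEAFRGFDTVGIGGKDASDNVGVKNERSGLTEPKAKSNGEKDEI
HPTNVSIETVLAEDVALMVKSSLGVSDLVTIVGYRQGVEVAHKYSKFLGRTGYDRILALT
GDRFVEVKFKLIAVADAALSYNGHMQLAEGANDTTPVNNKPPVPVNLGQVVGTMAGMRKA
IKAVDESARYSELDENAALDVTLNNKEGKDRLDGGAPMSRNATLQISIEHYRSLISDKVD
>XynC synthetic cellulosomal protein (300 aa)
FSRTLPPVSPICVEAVLAFAQPNAAKKSPHMPGRGQPFEGGSANGQATLPQFISINMVQQ
LEDVEAPLGGQELAELSSYLMDTGLGQWPDDVRTEILVIQFLFGGAGQNLEFKLLLSNDT
NNNYAYGANEELDLEVYKGMQCSNDKALAGGGGSSTSYVANYTLRFLDVFVFVGDIPEEE
VLLGLITAINAISSDQSVQTRNAKGQYCNEAAGVRLQGCGRFSHVRKLFYEYKNLIWAKS
HSSIGYLCDRLEAPTASSLIVLAAVAISGVTSYTCPGQISESGAFPQWMQGVKQHDSYTD
>OlpB synthetic cellulosomal protein (260 aa)
LEDKQSHKQLKESMANNEDAASSYIHSSWYYPAYVVGSKESTDGTSQDNDLMMGAVVSLA
MLRQGSQPCTAYYDADTAIYSTWIRPDLKVFDNNFERYYISCLERRAADRSSGLTQPEAS
VVVCKNKGPPSGMAKIGEGYLMYRTGQGEAFRNTITGCDDTHREINTVLSMLIYVALGAP
SYETNLVCVGYDFTKASAGAPPSFVDNWNYLTSTTKTADWTSTGRARMEIKGALSKQVVQ
TSGFGEPQVSQDDSLGLEIA
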